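"""Synthetic cohort, annotation and expression generators with known truth.

Every generator is a pure function of its configuration, including the
seed, so downstream stages can be tested against planted ground truth
without any external data.  The genotype model is a haplotype-copying
(Li-Stephens-style) chain: SNPs are organised in blocks sharing a single
allele frequency, and each haplotype allele copies its left neighbour with
probability ``ld_decay``, giving adjacent-SNP dosage correlation
``ld_decay`` and r^2 decaying geometrically with distance while exactly
preserving the marginal frequency.

Paired left/right traits are built as

    L = base + common + genetic_asym / 2 + noise_L
    R = base + common - genetic_asym / 2 + noise_R

where ``genetic_asym`` carries sparse SNP effects plus optional covariate
effects; the per-SNP effect sizes are solved from the configured fraction
of asymmetry-difference variance each causal SNP should explain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "PhaseSpec",
    "GeneratorConfig",
    "CohortTruth",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_gene_models",
    "gen_clade_map",
    "gen_species_expression",
    "gen_region_expression",
]


@dataclass(frozen=True)
class PhaseSpec:
    """Subject count and ancestry drift for one analysis phase.

    ``af_logit_shift_sd`` is the SD of a per-SNP normal shift applied on
    the logit scale to the block allele frequencies, emulating a
    replication cohort of different ancestry (phase 2); phase 3 reuses the
    discovery frequencies with a smaller sample.
    """

    n_subjects: int
    af_logit_shift_sd: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 2000
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_decay: float = 0.95
    seed: int = 0
    missing_rate: float = 0.0
    n_chromosomes: int = 4
    snp_spacing: int = 10_000
    phases: dict[int, PhaseSpec] = field(default_factory=dict)
    noise_sd: float = 1.0
    base_level: float = 10.0
    common_sd: float = 1.0
    n_instances: int = 1

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ValueError("ld_decay must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class CohortTruth:
    """Planted genetic architecture of the asymmetry component.

    ``variance_explained`` entries are fractions of the variance of the
    signed left-right difference D = L - R; their sum must stay below 1 so
    the residual measurement noise can absorb the remainder.
    ``causal_effects`` (trait units per alt allele) is filled in by
    :func:`gen_phenotypes` once allele frequencies are known.
    """

    causal_snp_ids: list[str]
    variance_explained: np.ndarray
    covariate_effects: dict[str, float] = field(default_factory=dict)
    causal_effects: np.ndarray | None = None

    def validate(self) -> None:
        v = np.asarray(self.variance_explained, dtype=float)
        if len(v) != len(self.causal_snp_ids):
            raise ValueError("variance_explained length must match causal_snp_ids")
        if np.any(v < 0) or np.any(v >= 1) or v.sum() >= 1:
            raise ValueError(
                "variance_explained entries must be in [0,1) with sum < 1"
            )


# ---------------------------------------------------------------------------
# genotypes


def _block_structure(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP block index and first-in-block flag."""
    block = np.arange(config.n_snps) // config.ld_block_size
    first = np.zeros(config.n_snps, dtype=bool)
    first[:: config.ld_block_size] = True
    return block, first


def _panel_metadata(config: GeneratorConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """SNP table plus per-SNP allele frequency (shared across phases)."""
    rng = np.random.default_rng([config.seed, 0x5EED])
    m = config.n_snps
    block, first = _block_structure(config)
    n_blocks = block[-1] + 1
    lo, hi = config.maf_range
    block_p = rng.uniform(lo, hi, size=n_blocks)
    # a block's frequency is a MAF; randomly let the alt allele be major
    flip = rng.random(n_blocks) < 0.5
    block_p = np.where(flip, 1.0 - block_p, block_p)
    p = block_p[block]

    n_chrom = min(config.n_chromosomes, m)
    chrom_of = (np.arange(m) * n_chrom) // m
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = (np.arange(idx.size) + 1) * config.snp_spacing
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt_shift = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": (chrom_of + 1).astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
    )
    return snps, p


def gen_genotypes(config: GeneratorConfig, phase: int = 1) -> GenotypeMatrix:
    """Simulate a dosage panel for one phase of the cohort.

    Phase 1 uses ``config.n_subjects``; other phases must appear in
    ``config.phases`` and may shift allele frequencies per SNP on the
    logit scale to emulate a different ancestry.
    """
    config.validate()
    snps, p = _panel_metadata(config)
    if phase == 1:
        n = config.n_subjects
    else:
        if phase not in config.phases:
            raise ValueError(f"phase {phase} not configured in config.phases")
        spec = config.phases[phase]
        n = spec.n_subjects
        if spec.af_logit_shift_sd > 0:
            rng_shift = np.random.default_rng([config.seed, phase, 0xA11E1E])
            eps = rng_shift.normal(0.0, spec.af_logit_shift_sd, size=len(p))
            logit = np.log(p / (1.0 - p)) + eps
            p = 1.0 / (1.0 + np.exp(-logit))

    rng = np.random.default_rng([config.seed, phase, 0x4A9])
    m = config.n_snps
    block, first = _block_structure(config)
    hap = np.empty((2 * n, m), dtype=np.uint8)
    B = config.ld_block_size
    starts = np.arange(0, m, B)
    # generate column-by-column within blocks, all blocks in parallel
    for offset in range(B):
        cols = starts + offset
        cols = cols[cols < m]
        fresh = rng.random((2 * n, cols.size)) < p[cols]
        if offset == 0:
            hap[:, cols] = fresh
        else:
            copy = rng.random((2 * n, cols.size)) < config.ld_decay
            hap[:, cols] = np.where(copy, hap[:, cols - 1], fresh)
    dos = (hap[0::2] + hap[1::2]).astype(np.float32)
    if config.missing_rate > 0:
        miss = rng.random(dos.shape) < config.missing_rate
        dos[miss] = np.nan
    subject_ids = np.array([f"P{phase}S{i:06d}" for i in range(n)])
    return GenotypeMatrix(subject_ids=subject_ids, snps=snps, dosages=dos)


# ---------------------------------------------------------------------------
# paired traits + covariates

COVARIATE_TERMS = ("age", "sex", "age2", "age_sex", "age2_sex")


def _covariate_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(40.0, 69.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 20))
    cov = pd.DataFrame({"age": age, "sex": sex})
    for k in range(20):
        cov[f"pc{k + 1}"] = pcs[:, k]
    return cov


def gen_phenotypes(
    genotypes: GenotypeMatrix,
    truth: CohortTruth,
    config: GeneratorConfig,
    phase: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired (L, R) trait table and covariate table for one phase.

    Returns ``(traits, covariates)``; ``traits`` has columns
    ``subject_id, left, right, instance``.  Fills ``truth.causal_effects``
    with the solved per-allele effect sizes.
    """
    truth.validate()
    n = genotypes.n_subjects
    rng = np.random.default_rng([config.seed, phase, 0xBEEF])
    cov = _covariate_table(n, rng)
    cov.insert(0, "subject_id", genotypes.subject_ids)

    v = np.asarray(truth.variance_explained, dtype=float)
    g_total = float(v.sum())
    snp_ids = list(genotypes.snps["snp_id"])
    cols = []
    for sid in truth.causal_snp_ids:
        try:
            cols.append(snp_ids.index(sid))
        except ValueError:
            raise KeyError(f"causal SNP {sid!r} absent from genotype panel") from None
    if cols:
        Gc = genotypes.dosages[:, cols].astype(float)
        col_mean = np.nanmean(Gc, axis=0)
        inds = np.where(np.isnan(Gc))
        Gc[inds] = np.take(col_mean, inds[1])
        var_d = np.var(Gc, axis=0)
        if g_total > 0 and config.noise_sd == 0:
            raise ValueError(
                "noise_sd must be positive when variance_explained > 0: "
                "the variance fractions are defined against the noisy L-R difference"
            )
        var_D = (
            2.0 * config.noise_sd**2 / (1.0 - g_total) if g_total > 0 else 0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.sqrt(np.where(var_d > 0, v * var_D / var_d, 0.0))
        truth.causal_effects = beta
        gasym = Gc @ beta
    else:
        truth.causal_effects = np.zeros(0)
        gasym = np.zeros(n)

    if truth.covariate_effects:
        terms = {
            "age": cov["age"].to_numpy(),
            "sex": cov["sex"].to_numpy(),
            "age2": cov["age"].to_numpy() ** 2,
            "age_sex": cov["age"].to_numpy() * cov["sex"].to_numpy(),
            "age2_sex": cov["age"].to_numpy() ** 2 * cov["sex"].to_numpy(),
        }
        for name, coef in truth.covariate_effects.items():
            if name not in terms:
                raise KeyError(f"unknown covariate term {name!r}")
            gasym = gasym + coef * terms[name]

    common = rng.normal(0.0, config.common_sd, size=n)
    frames = []
    for instance in range(1, config.n_instances + 1):
        eL = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        eR = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        left = config.base_level + common + 0.5 * gasym + eL
        right = config.base_level + common - 0.5 * gasym + eR
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": genotypes.subject_ids,
                    "left": left,
                    "right": right,
                    "instance": instance,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), cov


# ---------------------------------------------------------------------------
# gene models

SNP_GENE_CATEGORIES = ("single", "double", "intergenic")


def gen_gene_models(
    genotypes: GenotypeMatrix,
    config: GeneratorConfig,
    half_width: int = 50,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene intervals placed around each SNP by a fixed category cycle.

    SNP ``i`` (by panel order) falls inside exactly one gene, inside two
    overlapping genes, or in no gene, cycling single/double/intergenic.
    Intervals are 0-based half-open (BED convention) and narrow enough
    (``half_width`` each side) never to reach a neighbouring SNP.

    Returns ``(genes, categories)`` where ``categories`` maps snp_id to
    its planted category.
    """
    if 2 * half_width >= config.snp_spacing:
        raise ValueError("half_width must be smaller than half the SNP spacing")
    rng = np.random.default_rng([config.seed, 0x6E9E])
    records = []
    cats = []
    gid = 0
    for i, row in genotypes.snps.iterrows():
        cat = SNP_GENE_CATEGORIES[i % 3]
        cats.append(cat)
        start0 = int(row.pos) - 1  # 0-based position of the SNP
        if cat == "single":
            records.append((f"g{gid:05d}", row.chrom, start0 - half_width, start0 + half_width, "+-"[rng.integers(0, 2)]))
            gid += 1
        elif cat == "double":
            records.append((f"g{gid:05d}", row.chrom, start0 - half_width, start0 + 10, "+"))
            gid += 1
            records.append((f"g{gid:05d}", row.chrom, start0 - 10, start0 + half_width, "-"))
            gid += 1
    genes = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    genes["start"] = genes["start"].clip(lower=0)
    categories = pd.Series(cats, index=genotypes.snps["snp_id"].to_numpy(), name="category")
    return genes, categories


# ---------------------------------------------------------------------------
# clade maps


def gen_clade_map(
    clades: list[str],
    background_sizes: list[int],
    focal_size: int,
    enriched_clade: str | None = None,
    fold: float = 1.0,
    seed: int = 0,
):
    """Background gene->clade map plus a focal set with planted enrichment.

    Background genes are assigned to clades with exactly the stated
    counts.  Focal genes are drawn without replacement from the
    background, with the enriched clade's sampling probability multiplied
    by ``fold`` and the other clades rescaled proportionally.
    """
    from .clades import CladeMap

    if len(clades) != len(background_sizes):
        raise ValueError("clades and background_sizes must align")
    sizes = np.asarray(background_sizes, dtype=int)
    total = int(sizes.sum())
    if focal_size > total:
        raise ValueError("focal_size exceeds background size")
    props = sizes / total
    probs = props.copy()
    if enriched_clade is not None and fold != 1.0:
        e = clades.index(enriched_clade)
        pe = fold * props[e]
        if pe > 1.0:
            raise ValueError(
                f"fold * background proportion = {pe:.3f} exceeds 1 for clade {enriched_clade!r}"
            )
        probs = props * (1.0 - pe) / (1.0 - props[e])
        probs[e] = pe

    rng = np.random.default_rng([seed, 0xC1ADE])
    gene_ids = np.array([f"gene{i:06d}" for i in range(total)])
    assignment = pd.Series(np.repeat(clades, sizes), index=gene_ids, name="clade")
    # clade counts first (exactly the configured probabilities), then genes
    # uniformly within each clade, so large draws cannot deplete the target
    for _ in range(1000):
        counts = rng.multinomial(focal_size, probs / probs.sum())
        if (counts <= sizes).all():
            break
    else:
        raise ValueError("cannot place focal genes: a clade is too small")
    focal: list[str] = []
    offset = 0
    for c, size, k in zip(clades, sizes, counts):
        pool = gene_ids[offset : offset + size]
        focal.extend(rng.choice(pool, size=k, replace=False).tolist())
        offset += size
    cmap = CladeMap(clades=tuple(clades), assignment=assignment)
    return cmap, sorted(focal)


# ---------------------------------------------------------------------------
# expression tensors


def gen_species_expression(
    species: list[str],
    organs: list[str],
    stages: list[str],
    n_genes: int,
    focal_genes: list[str] | None = None,
    human_brain_shift: float = 0.0,
    replicates: int = 3,
    missing_cells: list[tuple[str, str, str]] | None = None,
    seed: int = 0,
    human: str = "human",
    brain: str = "brain",
    base_log2: float = 4.0,
    gene_sd: float = 1.5,
    organ_sd: float = 0.5,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Cross-species organ x stage expression with a planted brain shift.

    Expression is log-normal: a gene effect, an organ effect, a shared
    gene-by-organ interaction (identical in every species, so brain
    specificity differences are zero in expectation under the null), and
    replicate noise.  Focal genes get their human brain expression
    multiplied by ``2**human_brain_shift``.  ``missing_cells`` lists
    (species, organ, stage) combinations to omit entirely, emulating
    unavailable stages.

    Returns a long table: species, organ, stage, gene, replicate, value.
    """
    if brain not in organs:
        raise ValueError(f"{brain!r} must be among organs")
    if not math.isfinite(human_brain_shift):
        raise ValueError("human_brain_shift must be finite")
    focal = set(focal_genes or [])
    rng = np.random.default_rng([seed, 0xE59])
    genes = np.array([f"gene{i:06d}" for i in range(n_genes)])
    is_focal = np.isin(genes, sorted(focal))

    g_eff = rng.normal(0.0, gene_sd, size=n_genes)
    o_eff = {o: rng.normal(0.0, organ_sd) for o in organs}
    go_eff = {o: rng.normal(0.0, organ_sd, size=n_genes) for o in organs}
    s_eff = {s: rng.normal(0.0, 0.1) for s in stages}
    missing = set(missing_cells or [])

    frames = []
    for sp in species:
        for organ in organs:
            for stage in stages:
                if (sp, organ, stage) in missing:
                    continue
                mean_log2 = base_log2 + g_eff + o_eff[organ] + go_eff[organ] + s_eff[stage]
                if sp == human and organ == brain and human_brain_shift != 0.0:
                    mean_log2 = mean_log2 + np.where(is_focal, human_brain_shift, 0.0)
                noise = rng.normal(0.0, noise_sd, size=(replicates, n_genes))
                vals = 2.0 ** (mean_log2[None, :] + noise)
                frames.append(
                    pd.DataFrame(
                        {
                            "species": sp,
                            "organ": organ,
                            "stage": stage,
                            "gene": np.tile(genes, replicates),
                            "replicate": np.repeat(np.arange(1, replicates + 1), n_genes),
                            "value": vals.ravel(),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def gen_region_expression(
    donors: list[str],
    regions: list[str],
    n_genes: int,
    focal_genes: list[str] | None = None,
    asym_shift: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
    base_log2: float = 4.0,
    gene_sd: float = 1.5,
    lr_sd: float = 0.1,
    noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Donor x region x hemisphere expression with planted asymmetry.

    Each (donor, region, gene) draws a left-right log2 perturbation
    ``delta ~ N(0, (lr_sd * (1 + asym_shift * focal))^2)`` applied as
    +delta/2 to the left and -delta/2 to the right hemisphere, so
    ``asym_shift = 0`` makes focal genes exchangeable with the rest.

    Returns a long table: donor, region, hemisphere, gene, replicate, value.
    """
    if asym_shift < 0:
        raise ValueError("asym_shift must be >= 0")
    focal = set(focal_genes or [])
    rng = np.random.default_rng([seed, 0xA1])
    genes = np.array([f"gene{i:06d}" for i in range(n_genes)])
    is_focal = np.isin(genes, sorted(focal))
    g_eff = rng.normal(0.0, gene_sd, size=n_genes)
    sd_delta = lr_sd * (1.0 + asym_shift * is_focal)

    frames = []
    for donor in donors:
        for region in regions:
            delta = rng.normal(0.0, sd_delta)
            base = base_log2 + g_eff + rng.normal(0.0, 0.2, size=n_genes)
            for hemi, sign in (("left", 0.5), ("right", -0.5)):
                noise = rng.normal(0.0, noise_sd, size=(replicates, n_genes))
                vals = 2.0 ** (base[None, :] + sign * delta[None, :] + noise)
                frames.append(
                    pd.DataFrame(
                        {
                            "donor": donor,
                            "region": region,
                            "hemisphere": hemi,
                            "gene": np.tile(genes, replicates),
                            "replicate": np.repeat(np.arange(1, replicates + 1), n_genes),
                            "value": vals.ravel(),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
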