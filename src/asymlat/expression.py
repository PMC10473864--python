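"""Brain Specificity Index and cross-species / cross-tissue expression tests.

The Brain Specificity Index (BSI) of a gene in one species at one
developmental stage is

    BSI = log2( xbar_brain / mean_i(xbar_i) ),   i over non-brain organs,

where xbar_i is the replicate-mean expression in organ i.  Comparing two
species, only organs present in both and exceeding the expression
threshold (RPKM-like units) in both are used, and a one-tailed paired
Wilcoxon signed-rank test across genes asks whether BSI is higher in the
first species.  Tissue-level DEG-set enrichment uses the upper-tail
hypergeometric test with Bonferroni correction, and the per-gene brain
up/down classification uses a two-sided equal-variance t-test of brain
vs non-brain tissue means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BsiRecord",
    "cell_means",
    "compute_bsi",
    "bsi_table",
    "cross_species_bsi_test",
    "bsi_threshold_sweep",
    "deg_enrichment",
    "classify_brain_regulation",
]

EXPR_COLUMNS = ("species", "organ", "stage", "gene", "replicate", "value")


@dataclass
class BsiRecord:
    gene: str
    species: str
    stage: str
    organs_used: tuple[str, ...]
    bsi: float  # NaN when undefined
    reason: str = ""


def cell_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean expression per (species, organ, stage, gene)."""
    return (
        expr.groupby(["species", "organ", "stage", "gene"], sort=False)["value"]
        .mean()
        .reset_index()
    )


def _organ_matrix(expr: pd.DataFrame, species: str, stage: str) -> pd.DataFrame:
    """organs x genes matrix of replicate means for one species and stage."""
    sub = expr[(expr["species"] == species) & (expr["stage"] == stage)]
    return sub.pivot_table(index="organ", columns="gene", values="value", aggfunc="mean")


def compute_bsi(
    expr: pd.DataFrame,
    gene: str,
    species: str,
    stage: str,
    rpkm_min: float = 1.0,
    brain: str = "brain",
) -> BsiRecord:
    """BSI of one gene in one species at one stage.

    Non-brain organs enter only when present and with replicate mean
    above ``rpkm_min``; the record is missing when the brain cell is
    absent or no non-brain organ qualifies.
    """
    mat = _organ_matrix(expr, species, stage)
    if gene not in mat.columns or brain not in mat.index or np.isnan(mat.loc[brain, gene]):
        return BsiRecord(gene, species, stage, (), float("nan"), reason="brain cell missing")
    col = mat[gene]
    others = col.drop(index=brain)
    qualified = others[(~others.isna()) & (others > rpkm_min)]
    if qualified.empty:
        return BsiRecord(gene, species, stage, (brain,), float("nan"), reason="no qualifying non-brain organ")
    bsi = float(np.log2(col[brain] / qualified.mean()))
    return BsiRecord(gene, species, stage, (brain, *qualified.index), bsi)


def bsi_table(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    rpkm_min: float = 1.0,
    brain: str = "brain",
) -> pd.DataFrame:
    """Paired per-gene BSI for two species over their common usable organs.

    ``means_a``/``means_b`` are organs x genes replicate-mean matrices.
    For each gene, an organ is used only if present (non-missing) and
    above ``rpkm_min`` in BOTH species; the brain must qualify in both
    and at least one other organ must remain.  Returns a DataFrame with
    columns ``bsi_a, bsi_b`` indexed by gene (NaN where undefined).
    """
    common_organs = means_a.index.intersection(means_b.index)
    common_genes = means_a.columns.intersection(means_b.columns)
    A = means_a.loc[common_organs, common_genes]
    B = means_b.loc[common_organs, common_genes]
    if brain not in common_organs:
        raise ValueError(f"{brain!r} not shared between the two species")
    usable = (~A.isna()) & (~B.isna()) & (A > rpkm_min) & (B > rpkm_min)
    brain_ok = usable.loc[brain]
    others = [o for o in common_organs if o != brain]
    uo = usable.loc[others]
    n_other = uo.sum(axis=0)
    ok = brain_ok & (n_other >= 1)

    def _bsi(M: pd.DataFrame) -> pd.Series:
        other_mean = M.loc[others].where(uo).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(M.loc[brain] / other_mean)

    out = pd.DataFrame({"bsi_a": _bsi(A), "bsi_b": _bsi(B)})
    out[~ok] = np.nan
    return out


def cross_species_bsi_test(
    expr: pd.DataFrame,
    genes,
    species_a: str = "human",
    species_b: str = "",
    stage: str = "",
    rpkm_min: float = 1.0,
    brain: str = "brain",
) -> tuple[float, int]:
    """One-tailed paired Wilcoxon of BSI_a > BSI_b across genes.

    Genes with an undefined BSI in either species are dropped; exact
    zero differences follow the Wilcoxon convention (dropped), and an
    empty test reports P = 1.
    """
    ma = _organ_matrix(expr, species_a, stage)
    mb = _organ_matrix(expr, species_b, stage)
    tab = bsi_table(ma, mb, rpkm_min=rpkm_min, brain=brain)
    tab = tab.loc[tab.index.intersection(pd.Index(genes))].dropna()
    if tab.empty:
        raise ValueError("no usable genes for the cross-species comparison")
    diffs = (tab["bsi_a"] - tab["bsi_b"]).to_numpy()
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0, len(tab)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(nz, alternative="greater")
    return float(res.pvalue), int(len(tab))


def bsi_threshold_sweep(
    expr: pd.DataFrame,
    genes,
    stage: str,
    thresholds=(0.5, 1.0, 1.5),
    species_a: str = "human",
    brain: str = "brain",
) -> pd.DataFrame:
    """Cross-species BSI tests repeated over expression thresholds."""
    others = [s for s in expr["species"].unique() if s != species_a]
    rows = []
    for thr in thresholds:
        for sp in others:
            p, n = cross_species_bsi_test(
                expr, genes, species_a=species_a, species_b=sp, stage=stage,
                rpkm_min=thr, brain=brain,
            )
            rows.append({"species_b": sp, "threshold": thr, "p": p, "n_genes": n})
    return pd.DataFrame(rows, columns=["species_b", "threshold", "p", "n_genes"])


def deg_enrichment(focal, deg_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the focal set in DEG sets.

    ``deg_sets`` maps (tissue, direction) -> gene set.  Bonferroni
    correction is applied across all sets tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    focal = set(focal) & universe
    n_tests = len(deg_sets)
    rows = []
    for key, genes in deg_sets.items():
        tissue, direction = key
        s = set(genes) & universe
        k = len(focal & s)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(s), len(focal)))
        rows.append(
            {
                "tissue": tissue,
                "direction": direction,
                "overlap": k,
                "set_size": len(s),
                "p": p,
                "p_bonferroni": min(1.0, p * n_tests),
            }
        )
    out = pd.DataFrame(rows, columns=["tissue", "direction", "overlap", "set_size", "p", "p_bonferroni"])
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


def classify_brain_regulation(
    tissue_means: pd.DataFrame, brain_tissues, alpha: float = 0.05
) -> pd.Series:
    """Per-gene brain up/down/ns classification vs non-brain tissues.

    ``tissue_means`` is genes x tissues.  A two-sided equal-variance
    t-test compares brain and non-brain tissue means per gene; a gene is
    ``up`` or ``down`` by the sign of the mean difference when
    P < alpha / n_genes, else ``ns``.  Zero pooled variance yields ns.
    """
    brain_tissues = [t for t in brain_tissues if t in tissue_means.columns]
    other = [t for t in tissue_means.columns if t not in brain_tissues]
    if len(brain_tissues) < 2 or len(other) < 2:
        raise ValueError("need >= 2 brain and >= 2 non-brain tissues")
    A = tissue_means[brain_tissues].to_numpy(dtype=float)
    B = tissue_means[other].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=True)
    thr = alpha / len(tissue_means)
    diff = A.mean(axis=1) - B.mean(axis=1)
    cls = np.where(
        np.nan_to_num(res.pvalue, nan=1.0) < thr,
        np.where(diff > 0, "up", "down"),
        "ns",
    )
    degenerate = ~np.isfinite(res.pvalue)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero pooled variance set to ns",
            stacklevel=2,
        )
        cls[degenerate] = "ns"
    return pd.Series(cls, index=tissue_means.index, name="class")
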