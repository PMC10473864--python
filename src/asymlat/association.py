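"""Genotype QC, covariate residualization, per-SNP scan, LD clumping, GRM.

The association scan is ordinary least squares of the residualized,
normalized trait on alternate-allele dosage, one SNP at a time with
pairwise-complete subjects.  On unrelated cohorts this is the model a
mixed-model association method reduces to; the sparse-GRM utilities are
provided for the relatedness-pruning procedure.

Clumping follows the PLINK greedy algorithm: repeatedly take the most
significant unassigned SNP below ``p1`` as an index, absorb unassigned
SNPs below ``p2`` within the kb radius on the same chromosome with
dosage r^2 at or above the threshold, and report each index SNP as one
QTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "AssocResultSet",
    "ClumpResult",
    "RelatednessMatrix",
    "qc_genotypes",
    "hwe_pvalues",
    "build_covariate_design",
    "residualize",
    "assoc_scan",
    "inflation_factor",
    "ld_r2",
    "clump",
    "compute_grm",
    "sparsify_grm",
    "prune_related",
]

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


@dataclass
class AssocResultSet:
    """Per-SNP summary statistics plus the scan-level inflation factor."""

    table: pd.DataFrame  # columns: snp_id, chrom, pos, a1, a2, maf, n_used, beta, se, p

    @property
    def lambda_gc(self) -> float:
        return inflation_factor(self.table["p"].to_numpy())

    def to_tsv(self, path) -> None:
        out = self.table.rename(
            columns={
                "snp_id": "SNP", "chrom": "CHR", "pos": "POS", "a1": "A1",
                "a2": "A2", "maf": "MAF", "n_used": "N", "beta": "BETA",
                "se": "SE", "p": "P",
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AssocResultSet":
        t = pd.read_csv(path, sep="\t")
        t = t.rename(
            columns={
                "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "A1": "a1",
                "A2": "a2", "MAF": "maf", "N": "n_used", "BETA": "beta",
                "SE": "se", "P": "p",
            }
        )
        t["chrom"] = t["chrom"].astype(str)
        return cls(table=t)


@dataclass
class ClumpResult:
    index_snp: str
    index_p: float
    members: list[str] = field(default_factory=list)


@dataclass
class RelatednessMatrix:
    subject_ids: np.ndarray
    values: np.ndarray
    sparse: bool = False


# ---------------------------------------------------------------------------
# genotype QC


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Hardy-Weinberg 1-df chi-square P per SNP from hard-call counts."""
    d = G.dosages
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.where(
            (p > 0) & (q > 0),
            (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2,
            0.0,
        )
    return stats.chi2.sf(chi2, df=1)


def qc_genotypes(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    miss_max: float = 0.05,
) -> GenotypeMatrix:
    """Retain SNPs passing MAF, HWE, and missingness filters."""
    keep = (
        (G.maf() >= maf_min)
        & (hwe_pvalues(G) >= hwe_p_min)
        & (G.missing_rate() <= miss_max)
    )
    if not keep.any():
        warnings.warn("all SNPs removed by genotype QC", stacklevel=2)
    return G.take_snps(keep)


# ---------------------------------------------------------------------------
# covariates


def build_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand an age/sex/PC table into the scan's covariate terms.

    Produces age, sex, age^2, age x sex, age^2 x sex plus any ``pc*``
    columns present.  (Sex enters as a main effect alongside its
    interactions.)
    """
    age = covariates["age"].astype(float)
    sex = covariates["sex"].astype(float)
    design = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "age2": age**2,
            "age_sex": age * sex,
            "age2_sex": age**2 * sex,
        }
    )
    for col in covariates.columns:
        if col.startswith("pc"):
            design[col] = covariates[col].astype(float)
    return design


def residualize(y, covariates: pd.DataFrame) -> np.ndarray:
    """Least-squares residuals of y on intercept + covariate columns.

    Rows with missing y or covariates yield NaN residuals.  Constant
    columns are dropped; remaining rank deficiency raises an error naming
    the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    keep_cols = [j for j in range(X.shape[1]) if np.ptp(X[ok, j]) > 0]
    Xk = np.column_stack([np.ones(ok.sum())] + [X[ok, j] for j in keep_cols])
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(1, Xk.shape[1]):
            reduced = np.delete(Xk, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[keep_cols[j - 1]])
        raise ValueError(f"collinear covariate columns: {collinear}")
    coef, *_ = np.linalg.lstsq(Xk, y[ok], rcond=None)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - Xk @ coef
    return out


# ---------------------------------------------------------------------------
# per-SNP scan


def assoc_scan(residuals, G: GenotypeMatrix) -> AssocResultSet:
    """Per-SNP OLS of the residualized trait on dosage.

    Subjects missing either the trait or the dosage are excluded per SNP;
    monomorphic SNPs get missing statistics.
    """
    y = np.asarray(residuals, dtype=float)
    if y.shape[0] != G.n_subjects:
        raise ValueError("residuals not aligned to genotype subjects")
    d = G.dosages.astype(np.float32)
    y_ok = ~np.isnan(y)
    M = (~np.isnan(d) & y_ok[:, None]).astype(np.float32)
    dz = np.nan_to_num(d, nan=0.0) * M
    yv = np.where(y_ok, y, 0.0).astype(np.float32)

    n = M.sum(axis=0)
    Sx = dz.sum(axis=0)
    Sxx = (dz * dz).sum(axis=0)
    Sy = yv @ M
    Syy = (yv**2) @ M
    Sxy = yv @ dz

    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx_c = Sxx - Sx**2 / n
        Syy_c = Syy - Sy**2 / n
        Sxy_c = Sxy - Sx * Sy / n
        beta = Sxy_c / Sxx_c
        sse = Syy_c - beta * Sxy_c
        dfree = n - 2
        se = np.sqrt(np.maximum(sse, 0.0) / (dfree * Sxx_c))
        t = beta / se
    poly = (Sxx_c > 1e-8) & (n > 2)
    p = np.full(G.n_snps, np.nan)
    p[poly] = 2.0 * stats.t.sf(np.abs(t[poly]), dfree[poly])
    p[poly] = np.clip(p[poly], np.finfo(float).tiny, 1.0)
    beta = np.where(poly, beta, np.nan)
    se = np.where(poly, se, np.nan)

    snps = G.snps
    table = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "a1": snps["alt"].to_numpy(),
            "a2": snps["ref"].to_numpy(),
            "maf": G.maf(),
            "n_used": n.astype(int),
            "beta": beta.astype(float),
            "se": se.astype(float),
            "p": p,
        }
    )
    return AssocResultSet(table=table)


def inflation_factor(pvalues) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no non-missing P values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# LD and clumping


def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation over pairwise-complete subjects."""
    a = G.dosages[:, G.snp_index(snp_a)].astype(float)
    b = G.dosages[:, G.snp_index(snp_b)].astype(float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_one_vs_many(d: np.ndarray, j: int, cols: np.ndarray) -> np.ndarray:
    """r^2 between column j and each column in cols, pairwise complete."""
    x = d[:, j]
    out = np.empty(cols.size)
    for k, c in enumerate(cols):
        y = d[:, c]
        ok = ~np.isnan(x) & ~np.isnan(y)
        xs, ys = x[ok], y[ok]
        if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
            out[k] = np.nan
        else:
            r = np.corrcoef(xs, ys)[0, 1]
            out[k] = r * r
    return out


def clump(
    results: AssocResultSet,
    G: GenotypeMatrix,
    p1: float = 5e-8,
    p2: float = 5e-8,
    r2: float = 0.5,
    kb: float = 250.0,
) -> list[ClumpResult]:
    """Greedy LD clumping of the scan into index SNPs (QTLs).

    Equal P values are broken by (chromosome, position) ascending for
    deterministic output.  Clumps are returned ordered by index P.
    """
    t = results.table
    if len(t) != G.n_snps or not (t["snp_id"].to_numpy() == G.snps["snp_id"].to_numpy()).all():
        raise ValueError("results not aligned to genotype panel")
    p = t["p"].to_numpy(dtype=float)
    chrom = t["chrom"].to_numpy()
    pos = t["pos"].to_numpy(dtype=np.int64)
    snp_ids = t["snp_id"].to_numpy()
    d = G.dosages.astype(float)

    chrom_rank = pd.factorize(chrom, sort=True)[0]
    order = np.lexsort((pos, chrom_rank, p))  # p primary, then chrom, pos
    assigned = np.zeros(len(t), dtype=bool)
    radius = kb * 1000.0
    clumps: list[ClumpResult] = []
    for j in order:
        if assigned[j] or not (p[j] < p1):
            continue
        assigned[j] = True
        cand = np.flatnonzero(
            (~assigned)
            & (p < p2)
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= radius)
        )
        members: list[str] = []
        if cand.size:
            rr = _r2_one_vs_many(d, j, cand)
            hit = cand[np.nan_to_num(rr, nan=-1.0) >= r2]
            assigned[hit] = True
            members = snp_ids[hit].tolist()
        clumps.append(ClumpResult(index_snp=str(snp_ids[j]), index_p=float(p[j]), members=members))
    return clumps


# ---------------------------------------------------------------------------
# GRM and relatedness


def compute_grm(G: GenotypeMatrix) -> RelatednessMatrix:
    """GRM from standardized dosages: Z Z^T / M, Z = (d - 2p)/sqrt(2p(1-p))."""
    if G.n_subjects < 2:
        raise ValueError("GRM needs at least 2 subjects")
    d = G.dosages.astype(float)
    p = G.alt_freq()
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1) & (np.nanvar(d, axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for GRM")
    dp = d[:, poly]
    pp = p[poly]
    Z = (dp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    Z = np.nan_to_num(Z, nan=0.0)  # missing calls contribute nothing
    grm = (Z @ Z.T) / poly.sum()
    return RelatednessMatrix(subject_ids=G.subject_ids, values=grm, sparse=False)


def sparsify_grm(grm: RelatednessMatrix, cutoff: float = 0.05) -> RelatednessMatrix:
    """Zero off-diagonal relatedness entries below the cutoff."""
    v = grm.values.copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    v[off & (v < cutoff)] = 0.0
    return RelatednessMatrix(subject_ids=grm.subject_ids, values=v, sparse=True)


def prune_related(grm_sparse: RelatednessMatrix, max_relatives: int = 100) -> list[str]:
    """Subjects removed so none keeps > max_relatives nonzero relatives.

    Iteratively removes the subject with the largest relative count
    (ties: first in subject order), recounting after each removal.
    """
    v = grm_sparse.values != 0
    np.fill_diagonal(v, False)
    active = np.ones(v.shape[0], dtype=bool)
    removed: list[str] = []
    while True:
        counts = (v & active[None, :]).sum(axis=1)
        counts[~active] = -1
        worst = int(np.argmax(counts))
        if counts[worst] <= max_relatives:
            break
        active[worst] = False
        removed.append(str(grm_sparse.subject_ids[worst]))
    return removed
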