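"""Replication concordance statistics between a discovery and a replication scan.

Three indexes quantify agreement of two association scans of the same
trait: Pearson correlation of effect sizes over the top clumped SNPs,
the sign concordance rate (SCR) with a binomial test at p0 = 0.5, and
the count of discovery QTLs re-reaching Bonferroni significance in the
replication scan with a binomial test at p0 = alpha/n.  All binomial
tests are one-sided upper tails (the question is excess concordance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ReplicationSummary",
    "sign_concordance",
    "beta_correlation",
    "qtl_replication",
]


@dataclass
class ReplicationSummary:
    scr: float
    scr_p: float
    beta_r: float
    beta_r_p: float
    n_trials: int
    n_qtls_tested: int
    n_qtls_replicated: int
    qtl_p: float


def sign_concordance(beta_disc, beta_rep) -> tuple[float, float]:
    """SCR and its one-sided binomial P (p0 = 0.5).

    Pairs where either beta is zero or missing are excluded from the
    trial count.
    """
    a = np.asarray(beta_disc, dtype=float)
    b = np.asarray(beta_rep, dtype=float)
    if a.shape != b.shape:
        raise ValueError("beta vectors must align")
    ok = ~np.isnan(a) & ~np.isnan(b) & (a != 0) & (b != 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no usable sign pairs")
    k = int((np.sign(a[ok]) == np.sign(b[ok])).sum())
    scr = k / n
    scr_p = float(stats.binom.sf(k - 1, n, 0.5))
    return scr, scr_p


def beta_correlation(beta_disc, beta_rep) -> tuple[float, float]:
    """Pearson correlation of effect sizes with its two-sided P.

    Returns (nan, nan) when either vector has zero variance.  The caller
    selects the SNP set, typically the top 200 index SNPs from clumping
    the discovery scan at p1 = p2 = 1e-4.
    """
    a = np.asarray(beta_disc, dtype=float)
    b = np.asarray(beta_rep, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 aligned pairs")
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def qtl_replication(rep_pvalues, alpha: float = 0.05) -> tuple[int, float, float]:
    """Bonferroni QTL replication count and its one-sided binomial P.

    ``rep_pvalues`` are replication-scan P values of the discovery index
    SNPs present in the replication scan.  Returns
    (k, threshold, qtl_p) with threshold = alpha/n and
    qtl_p = P(X >= k | n, alpha/n).
    """
    p = np.asarray(rep_pvalues, dtype=float)
    n = p.size
    if n < 1:
        raise ValueError("need at least one replication P value")
    threshold = alpha / n
    k = int(np.nansum(p < threshold))
    qtl_p = float(stats.binom.sf(k - 1, n, threshold))
    return k, threshold, qtl_p


def summarize_replication(
    disc_betas, rep_betas, rep_pvalues_of_indices, alpha: float = 0.05
) -> ReplicationSummary:
    """Bundle the three indexes for one discovery/replication pairing."""
    scr, scr_p = sign_concordance(disc_betas, rep_betas)
    r, r_p = beta_correlation(disc_betas, rep_betas)
    k, _, qtl_p = qtl_replication(rep_pvalues_of_indices, alpha=alpha)
    a = np.asarray(disc_betas, dtype=float)
    b = np.asarray(rep_betas, dtype=float)
    n_trials = int((~np.isnan(a) & ~np.isnan(b) & (a != 0) & (b != 0)).sum())
    return ReplicationSummary(
        scr=scr,
        scr_p=scr_p,
        beta_r=r,
        beta_r_p=r_p,
        n_trials=n_trials,
        n_qtls_tested=len(np.asarray(rep_pvalues_of_indices)),
        n_qtls_replicated=k,
        qtl_p=qtl_p,
    )
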