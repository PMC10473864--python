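"""Angular left-right asymmetry traits, trait-level QC, and normalization.

For a paired trait (L, R) measured in mirror regions of the two
hemispheres, the signed angular asymmetry is

    theta = arcsin( (L - R) / sqrt(2 (L^2 + R^2)) ),

the deviation angle of the point (L, R) from the diagonal L = R.  Four
"plans" are derived per pair:

    I   signed angle on raw values
    II  |plan I|
    III signed angle on z-standardized values L_s, R_s
    IV  |plan III|

The angle is scale invariant, antisymmetric in (L, R), bounded by pi/4 in
absolute value when both sides are nonnegative, and rank-equivalent to the
traditional index (L - R)/(L + R) on strictly positive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "PLANS",
    "AsymmetryTrait",
    "compute_asymmetry",
    "traditional_index",
    "qc_trait",
    "normalize_trait",
    "expand_trait_pairs",
]

PLANS = ("I", "II", "III", "IV")


@dataclass
class AsymmetryTrait:
    plan: str
    values: np.ndarray
    qc_status: str = "unchecked"
    normalized: np.ndarray | None = None
    subject_ids: np.ndarray | None = None


def _zstandardize(x: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(x)
    if ok.sum() < 2 or np.unique(x[ok]).size < 2:
        raise ValueError("standardization undefined: fewer than 2 distinct values")
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    return (x - mu) / sd


def compute_asymmetry(left, right, plan: str = "I", subject_ids=None) -> AsymmetryTrait:
    """Angular asymmetry of each (L, R) pair under one plan.

    Subjects with L = R = 0 (after standardization for plans III/IV) have
    no defined direction and yield NaN.
    """
    if plan not in PLANS:
        raise ValueError(f"plan must be one of {PLANS}, got {plan!r}")
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    if L.shape != R.shape:
        raise ValueError("left and right must have equal length")
    if L.size == 0:
        raise ValueError("empty trait pair")
    if plan in ("III", "IV"):
        L, R = _zstandardize(L), _zstandardize(R)
    denom = np.sqrt(2.0 * (L**2 + R**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = np.where(denom > 0, (L - R) / denom, np.nan)
    theta = np.arcsin(np.clip(arg, -1.0, 1.0))
    if plan in ("II", "IV"):
        theta = np.abs(theta)
    return AsymmetryTrait(plan=plan, values=theta, subject_ids=subject_ids)


def traditional_index(left, right) -> np.ndarray:
    """Classical laterality index (L - R)/(L + R); NaN where L + R = 0."""
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    s = L + R
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s != 0, (L - R) / s, np.nan)
    return out


def qc_trait(
    trait: AsymmetryTrait,
    min_n: int = 1000,
    max_identical_frac: float = 0.5,
) -> AsymmetryTrait:
    """Flag traits that are too small or dominated by a single value.

    ``dropped(small_sample)`` when fewer than ``min_n`` non-missing
    values remain; ``dropped(degenerate)`` when the modal value accounts
    for more than ``max_identical_frac`` of the non-missing values.
    """
    vals = trait.values[~np.isnan(trait.values)]
    if vals.size < min_n:
        status = "dropped(small_sample)"
    else:
        _, counts = np.unique(vals, return_counts=True)
        if counts.max() / vals.size > max_identical_frac:
            status = "dropped(degenerate)"
        else:
            status = "kept"
    trait.qc_status = status
    return trait


def normalize_trait(values, method: str = "auto") -> np.ndarray:
    """Rank-based inverse-normal transform or z-scaling.

    ``rank_int`` maps average ranks r to standard-normal quantiles at
    (r - 0.5)/n over the non-missing values; ``zscale`` is
    (x - mean)/sd.  ``auto`` uses rank_int unless more than 25% of the
    non-missing values are tied at a single value (a poor candidate for a
    rank transform), in which case it falls back to zscale.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    v = x[ok]
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("normalization undefined: all values identical")
    if method == "auto":
        _, counts = np.unique(v, return_counts=True)
        method = "zscale" if counts.max() / v.size > 0.25 else "rank_int"
    out = np.full_like(x, np.nan)
    if method == "rank_int":
        ranks = stats.rankdata(v, method="average")
        out[ok] = ndtri((ranks - 0.5) / v.size)
    elif method == "zscale":
        out[ok] = (v - v.mean()) / v.std(ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def expand_trait_pairs(pairs, plans=PLANS) -> pd.DataFrame:
    """Enumerate the derived asymmetry traits for a set of L/R pairs.

    ``pairs`` is an iterable of pair identifiers (or a DataFrame with a
    ``pair_id`` column).  Each pair expands into one trait per plan.
    """
    if isinstance(pairs, pd.DataFrame):
        pair_ids = pairs["pair_id"].tolist()
    else:
        pair_ids = list(pairs)
    records = [
        {"pair_id": pid, "plan": plan, "trait_id": f"{pid}_plan{plan}"}
        for pid in pair_ids
        for plan in plans
    ]
    return pd.DataFrame(records, columns=["pair_id", "plan", "trait_id"])
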