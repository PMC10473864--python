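"""Asymmetry level (AL) of hemispheric gene expression and group tests.

For replicate-mean expression L and R of a gene in the left and right
versions of one brain region,

    AL = |L - R| / sqrt(2 (L^2 + R^2)),

the absolute sine of the angular asymmetry (no arcsine applied).  Over
nonnegative expression AL is bounded by 1/sqrt(2); over unconstrained
real pairs its supremum is 1 (at L = -R).  Group testing asks, via a
one-sided rank-sum test, whether a focal gene set has higher AL than the
remaining genes, overall or per region with Benjamini-Hochberg
correction across regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "region_al",
    "relative_normalize",
    "al_table",
    "al_group_test",
    "donor_average",
]


def region_al(left_reps, right_reps, floor: float = 1e-7) -> float:
    """AL from replicate vectors of one (region, gene) pair.

    Replicate values below ``floor`` (already on the relative-abundance
    scale) are treated as missing; a side with no surviving replicate,
    or L = R = 0, yields NaN.
    """
    L = np.asarray(left_reps, dtype=float)
    R = np.asarray(right_reps, dtype=float)
    L = L[~np.isnan(L) & (np.abs(L) >= floor)]
    R = R[~np.isnan(R) & (np.abs(R) >= floor)]
    if L.size == 0 or R.size == 0:
        return float("nan")
    lm, rm = L.mean(), R.mean()
    denom = np.sqrt(2.0 * (lm**2 + rm**2))
    if denom == 0.0:
        return float("nan")
    return float(abs(lm - rm) / denom)


def relative_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Express each value relative to its sample's total across genes.

    A sample is one (donor, region, hemisphere, replicate) measurement.
    """
    out = df.copy()
    totals = out.groupby(["donor", "region", "hemisphere", "replicate"])["value"].transform("sum")
    out["value"] = out["value"] / totals
    return out


def al_table(
    df: pd.DataFrame, floor: float = 1e-7, normalize: bool = True
) -> pd.DataFrame:
    """Per (donor, region, gene) AL from a long hemispheric table.

    ``df`` columns: donor, region, hemisphere (left/right), gene,
    replicate, value.  Values are first put on the relative scale (per
    sample) unless ``normalize`` is False, then values below ``floor``
    are masked, replicates averaged, and AL computed.
    """
    d = relative_normalize(df) if normalize else df.copy()
    d.loc[d["value"] < floor, "value"] = np.nan
    means = (
        d.groupby(["donor", "region", "gene", "hemisphere"])["value"]
        .mean()
        .unstack("hemisphere")
    )
    L = means.get("left")
    R = means.get("right")
    if L is None or R is None:
        raise ValueError("hemisphere column must contain 'left' and 'right'")
    denom = np.sqrt(2.0 * (L**2 + R**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        al = (L - R).abs() / denom
    al[denom == 0] = np.nan
    out = al.rename("al").reset_index()
    return out


def al_group_test(
    al_values: pd.DataFrame | pd.Series,
    focal,
    scope: str = "overall",
) -> float | pd.DataFrame:
    """One-sided rank-sum test of focal AL exceeding the other genes'.

    ``overall`` pools every non-missing AL and returns a single P.
    ``per_region`` (requires a DataFrame with a ``region`` column)
    returns a table of per-region P values with BH adjustment across
    regions.
    """
    focal = set(focal)

    def _test(vals: pd.Series, genes: pd.Series) -> float:
        mask = genes.isin(focal)
        a = vals[mask].dropna()
        b = vals[~mask].dropna()
        if a.empty or b.empty:
            return float("nan")
        return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)

    if isinstance(al_values, pd.Series):
        frame = al_values.rename("al").reset_index().rename(columns={"index": "gene"})
    else:
        frame = al_values
    if scope == "overall":
        return _test(frame["al"], frame["gene"])
    if scope == "per_region":
        rows = []
        for region, sub in frame.groupby("region"):
            rows.append({"region": region, "p": _test(sub["al"], sub["gene"])})
        table = pd.DataFrame(rows)
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        table["p_bh"] = adj
        return table
    raise ValueError(f"unknown scope {scope!r}")


def donor_average(
    al_donor1: pd.DataFrame,
    al_donor2: pd.DataFrame,
    strict_both: bool = False,
) -> tuple[pd.Series, float, float]:
    """Cross-donor AL averaging over shared regions plus their agreement.

    Inputs are per-donor tables with columns region, gene, al.  Returns
    ``(per_gene_average, pearson_r, pearson_p)`` where the correlation
    stacks (gene, region) AL pairs present in both donors, and the
    per-gene average takes each donor's mean over shared regions and
    then the cross-donor mean.  When one donor's per-gene mean is
    missing, the present donor's value is used unless ``strict_both``.
    """
    shared = sorted(set(al_donor1["region"]) & set(al_donor2["region"]))
    if not shared:
        raise ValueError("no shared regions between donors")
    a = al_donor1[al_donor1["region"].isin(shared)].set_index(["gene", "region"])["al"]
    b = al_donor2[al_donor2["region"].isin(shared)].set_index(["gene", "region"])["al"]
    paired = pd.concat({"a": a, "b": b}, axis=1).dropna()
    if len(paired) >= 3:
        r, p = stats.pearsonr(paired["a"], paired["b"])
    else:
        r, p = float("nan"), float("nan")
    ga = a.groupby("gene").mean()
    gb = b.groupby("gene").mean()
    both = pd.concat({"a": ga, "b": gb}, axis=1)
    if strict_both:
        avg = both.dropna().mean(axis=1)
    else:
        avg = both.mean(axis=1, skipna=True)
    return avg.rename("al"), float(r), float(p)
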