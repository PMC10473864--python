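"""Clade-of-origin (gene-age) enrichment of a focal gene set.

Phylostratigraphy assigns each background gene to the lineage clade at
which it is inferred to have emerged (ordered most ancient to most
recent).  Enrichment of a focal set in a clade is a one-sided binomial
upper tail against the background clade proportion.  The stepwise
procedure repeatedly removes the most significant clade's genes from
both the focal and background sets (renormalizing proportions) to
address the nonindependence of per-clade tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CladeMap",
    "clade_binomial",
    "enrich_all_clades",
    "degenerate_tree",
    "stepwise_enrichment",
]


@dataclass
class CladeMap:
    """Ordered clades (ancient -> recent) and gene -> clade assignments."""

    clades: tuple[str, ...]
    assignment: pd.Series  # index gene_id, values clade label

    def __post_init__(self) -> None:
        unknown = set(self.assignment.unique()) - set(self.clades)
        if unknown:
            raise ValueError(f"assignments to unlisted clades: {sorted(unknown)}")

    def proportions(self) -> pd.Series:
        counts = self.assignment.value_counts()
        props = counts.reindex(self.clades, fill_value=0) / len(self.assignment)
        return props

    @classmethod
    def from_tsv(cls, path, clades: list[str]) -> "CladeMap":
        t = pd.read_csv(path, sep="\t")
        return cls(clades=tuple(clades), assignment=pd.Series(t["clade"].to_numpy(), index=t["gene_id"], name="clade"))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": self.assignment.index, "clade": self.assignment.to_numpy()}
        ).to_csv(path, sep="\t", index=False)


def _usable_focal(focal, cmap: CladeMap) -> list[str]:
    focal = list(focal)
    known = set(cmap.assignment.index)
    missing = [g for g in focal if g not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} focal genes absent from the clade map were excluded",
            stacklevel=3,
        )
    return [g for g in focal if g in known]


def clade_binomial(focal, cmap: CladeMap, clade: str) -> float:
    """One-sided binomial enrichment P of the focal set in one clade."""
    if clade not in cmap.clades:
        raise ValueError(f"clade {clade!r} not in map")
    focal = _usable_focal(focal, cmap)
    n = len(focal)
    if n == 0:
        raise ValueError("no focal genes overlap the clade map")
    k = int((cmap.assignment.loc[focal] == clade).sum())
    p = float(cmap.proportions()[clade])
    return float(stats.binom.sf(k - 1, n, p))


def enrich_all_clades(focal, cmap: CladeMap, alpha: float = 0.05) -> pd.DataFrame:
    """Per-clade binomial enrichment table with significance flags.

    Flags are unadjusted P < alpha, matching the per-clade testing
    convention of gene-age enrichment displays.
    """
    focal = _usable_focal(focal, cmap)
    n = len(focal)
    if n == 0:
        raise ValueError("no focal genes overlap the clade map")
    props = cmap.proportions()
    focal_clades = cmap.assignment.loc[focal]
    rows = []
    for clade in cmap.clades:
        k = int((focal_clades == clade).sum())
        p = float(props[clade])
        pv = float(stats.binom.sf(k - 1, n, p))
        rows.append(
            {
                "clade": clade,
                "k": k,
                "n": n,
                "background_p": p,
                "binom_p": pv,
                "significant": pv < alpha,
            }
        )
    return pd.DataFrame(rows)


def degenerate_tree(cmap: CladeMap, boundary: str = "Tetrapoda", label: str = "ancient") -> CladeMap:
    """Merge all clades strictly more ancient than ``boundary`` into one.

    Gene counts are conserved; the clade order is preserved with the
    merged "ancient" clade first.  No merge occurs when the boundary is
    the most ancient clade.
    """
    if boundary not in cmap.clades:
        raise ValueError(f"boundary clade {boundary!r} not in map")
    b = cmap.clades.index(boundary)
    if b == 0:
        return CladeMap(clades=cmap.clades, assignment=cmap.assignment.copy())
    old = cmap.clades[:b]
    new_clades = (label,) + cmap.clades[b:]
    remap = {c: (label if c in old else c) for c in cmap.clades}
    return CladeMap(clades=new_clades, assignment=cmap.assignment.map(remap))


def stepwise_enrichment(focal, cmap: CladeMap, alpha: float = 0.05) -> list[tuple[str, float]]:
    """Iterative most-significant-clade selection with gene removal.

    Each round tests every remaining clade; if the minimum P is below
    ``alpha`` that clade is recorded and its genes are removed from both
    the focal and background sets (background proportions renormalize
    over the remaining clades).  Ties in minimum P go to the more
    ancient clade.  Stops when no clade reaches ``alpha`` or either set
    empties.
    """
    focal = _usable_focal(focal, cmap)
    assignment = cmap.assignment.copy()
    clades = list(cmap.clades)
    selected: list[tuple[str, float]] = []
    while focal and clades:
        sub = CladeMap(clades=tuple(clades), assignment=assignment)
        table = enrich_all_clades(focal, sub, alpha=alpha)
        best_p = table["binom_p"].min()
        if not (best_p < alpha):
            break
        # ties resolved toward the more ancient clade (table preserves order)
        best = table.loc[table["binom_p"] == best_p].iloc[0]["clade"]
        selected.append((str(best), float(best_p)))
        focal = [g for g in focal if assignment.loc[g] != best]
        assignment = assignment[assignment != best]
        clades = [c for c in clades if c != best]
    return selected
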