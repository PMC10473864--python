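"""Interval-based SNP-to-gene assignment with multi-gene and intergenic drops.

A SNP maps to a gene only when it falls inside exactly one gene interval;
SNPs inside two or more (overlapping) genes are dropped, as are
intergenic SNPs.  Gene sets from two annotation routes are merged by
simple set union.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_bed",
    "write_bed",
    "map_snp_to_gene",
    "map_snps",
    "merge_annotations",
]

BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of gene intervals (0-based half-open)."""
    genes = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes.columns = BED_COLUMNS[: genes.shape[1]]
    genes["chrom"] = genes["chrom"].astype(str)
    return genes[[c for c in ("gene_id", "chrom", "start", "end", "strand") if c in genes.columns]]


def write_bed(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    out["score"] = 0
    cols = [c for c in BED_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def _overlapping(genes: pd.DataFrame, chrom: str, pos0: int, flank: int) -> pd.DataFrame:
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    return sub[(sub["start"] - flank <= pos0) & (pos0 < sub["end"] + flank)]


def map_snp_to_gene(
    chrom: str, pos: int, genes: pd.DataFrame, flank: int = 0
) -> str | None:
    """Gene containing the SNP, or None on multi-gene or intergenic hits.

    ``pos`` is 1-based (VCF convention); gene intervals are 0-based
    half-open.  ``flank`` extends each interval symmetrically for
    sensitivity analyses (default 0: no nearest-gene fallback).
    """
    if str(chrom) not in set(genes["chrom"].astype(str)):
        warnings.warn(f"chromosome {chrom!r} absent from gene set", stacklevel=2)
        return None
    hits = _overlapping(genes, chrom, int(pos) - 1, flank)
    if len(hits) == 1:
        return str(hits["gene_id"].iloc[0])
    return None


def map_snps(snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 0) -> pd.Series:
    """Vectorized mapping of a SNP table (snp_id, chrom, pos) to gene ids."""
    out = {}
    known = set(genes["chrom"].astype(str))
    for _, row in snps.iterrows():
        if str(row["chrom"]) not in known:
            out[row["snp_id"]] = None
            continue
        hits = _overlapping(genes, row["chrom"], int(row["pos"]) - 1, flank)
        out[row["snp_id"]] = str(hits["gene_id"].iloc[0]) if len(hits) == 1 else None
    return pd.Series(out, name="gene_id")


def merge_annotations(set_a, set_b) -> list[str]:
    """Deduplicated union of two gene-id collections, sorted by identifier."""
    return sorted(set(set_a) | set(set_b))
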