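"""Dosage genotype container with VCF round-trip support.

Genotypes are held as a dense subjects x SNPs matrix of alternate-allele
dosages in {0, 1, 2}, with ``NaN`` marking missing hard calls.  SNP
metadata (chromosome, 1-based position, ref/alt alleles) travels alongside
the matrix.  Only biallelic SNPs are representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Subjects x biallelic SNPs dosage matrix.

    Parameters
    ----------
    subject_ids : array of str
        One identifier per row of ``dosages``.
    snps : pandas.DataFrame
        Columns ``snp_id, chrom, pos, ref, alt``; ``pos`` is 1-based and
        strictly increasing within a chromosome.
    dosages : ndarray, shape (n_subjects, n_snps)
        Alternate-allele dosages in {0, 1, 2}; NaN for missing calls.
    """

    subject_ids: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.subject_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table lacks columns {missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (in [0, 0.5])."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the selected SNP columns."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            subject_ids=self.subject_ids,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_subjects(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            subject_ids=self.subject_ids[idx],
            snps=self.snps,
            dosages=self.dosages[idx, :],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snps["snp_id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not present")
        return int(hits[0])

    # -- VCF round trip ---------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a minimal VCFv4.2 file with GT hard calls ("./." missing)."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.subject_ids))
                + "\n"
            )
            snps = self.snps
            for j in range(self.n_snps):
                row = snps.iloc[j]
                calls = [
                    "./." if np.isnan(d) else gt_codes[float(d)]
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                    "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a biallelic hard-call VCF produced by :meth:`to_vcf`."""
        meta = {"snp_id": [], "chrom": [], "pos": [], "ref": [], "alt": []}
        rows = []
        subject_ids: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    subject_ids = fields[9:]
                    continue
                chrom, pos, snp_id, ref, alt = fields[:5]
                if "," in alt:
                    raise ValueError(f"multiallelic record {snp_id} not supported")
                meta["snp_id"].append(snp_id)
                meta["chrom"].append(chrom)
                meta["pos"].append(int(pos))
                meta["ref"].append(ref)
                meta["alt"].append(alt)
                dos = []
                for call in fields[9:]:
                    gt = call.split(":", 1)[0]
                    if "." in gt:
                        dos.append(np.nan)
                    else:
                        dos.append(float(sum(int(a) for a in gt.replace("|", "/").split("/"))))
                rows.append(dos)
        dosages = np.asarray(rows, dtype=np.float32).T if rows else np.empty((len(subject_ids), 0))
        return cls(
            subject_ids=np.asarray(subject_ids),
            snps=pd.DataFrame(meta),
            dosages=dosages,
        )
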