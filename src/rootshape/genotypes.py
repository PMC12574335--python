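"""Genotype container and VCF input/output.

Dosages are stored accession x marker as floats in {0, 1, 2} counting copies
of the alternate allele, with ``nan`` marking missing calls. Positions are
1-based and strictly increasing within a chromosome, the usual convention for
GBS-derived SNP matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass
class GenotypeMatrix:
    """Accession x marker dosage matrix with marker coordinates.

    Parameters
    ----------
    dosage : ndarray (n_accessions, n_markers)
        Alternate-allele dosage in {0, 1, 2}; ``nan`` is missing.
    chrom : ndarray of str
        Chromosome name per marker.
    pos : ndarray of int
        1-based physical position per marker.
    ref, alt : ndarray of str
        Reference and alternate alleles.
    accessions : list of str
        Accession identifiers, one per dosage row.
    groups : dict, optional
        Accession id -> group label (crop type or assigned population).
    """

    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    accessions: list
    groups: dict | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (accessions x markers)")
        n, m = self.dosage.shape
        if len(self.accessions) != n:
            raise ValueError("accession ids do not match dosage rows")
        for arr, name in [(self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")]:
            if len(arr) != m:
                raise ValueError(f"{name} does not match dosage columns")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValueError("dosages must lie in [0, 2] or be nan")

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.pos)],
                        dtype=object)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the marker mean."""
        d = self.dosage.copy()
        if np.any(np.isnan(d)):
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.dosage[:, index], self.chrom[index],
                              self.pos[index], self.ref[index],
                              self.alt[index], list(self.accessions),
                              self.groups)

    def take_accessions(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        acc = [self.accessions[i] for i in index]
        groups = None
        if self.groups is not None:
            groups = {a: self.groups[a] for a in acc if a in self.groups}
        return GenotypeMatrix(self.dosage[index], self.chrom, self.pos,
                              self.ref, self.alt, acc, groups)

    def subset_by_group(self, labels) -> "GenotypeMatrix":
        if self.groups is None:
            raise ValueError("no group labels attached")
        labels = set(np.atleast_1d(labels))
        keep = [i for i, a in enumerate(self.accessions)
                if self.groups.get(a) in labels]
        if not keep:
            raise ValueError(f"no accessions in groups {sorted(labels)}")
        return self.take_accessions(keep)

    def group_array(self) -> np.ndarray:
        if self.groups is None:
            raise ValueError("no group labels attached")
        return np.array([self.groups[a] for a in self.accessions], dtype=object)

    # ------------------------------------------------------------------
    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 (GT only, unphased)."""
        path = Path(path)
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            for c in pd.unique(self.chrom.astype(str)):
                ln = int(self.pos[self.chrom.astype(str) == c].max()) + 1
                fh.write(f"##contig=<ID={c},length={ln}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.accessions)) + "\n")
            for j in range(self.n_markers):
                gts = [code.get(self.dosage[i, j], "./.")
                       for i in range(self.n_accessions)]
                fh.write(f"{self.chrom[j]}\t{self.pos[j]}\t"
                         f"{self.chrom[j]}_{self.pos[j]}\t{self.ref[j]}\t"
                         f"{self.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts)
                         + "\n")

    @classmethod
    def from_vcf(cls, path, groups: dict | None = None) -> "GenotypeMatrix":
        """Load biallelic SNPs from a VCF via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        accessions = list(vcf.samples)
        chrom, pos, ref, alt, rows = [], [], [], [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0])
            g = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3=missing
            g[g == 3] = np.nan
            rows.append(g)
        vcf.close()
        dosage = np.array(rows, dtype=float).T if rows else \
            np.empty((len(accessions), 0))
        return cls(dosage, np.array(chrom, dtype=object),
                   np.array(pos, dtype=np.int64),
                   np.array(ref, dtype=object), np.array(alt, dtype=object),
                   accessions, groups)
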