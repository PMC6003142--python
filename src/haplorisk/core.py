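"""Shared data model for the case-control haplotype association toolkit.

Genotypes are held as minor-allele dosage matrices (samples x SNPs) with
``-1`` marking a missing call.  Phenotypes and variant annotations are thin
wrappers around pandas DataFrames with a controlled vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: controlled vocabulary for categorical covariates
STATUS_LEVELS = ("control", "case")
SEX_LEVELS = ("female", "male")
EXPOSURE_LEVELS = ("never", "ever")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypeTable:
    """Unphased biallelic genotypes as minor-allele dosages.

    Parameters
    ----------
    sample_ids : list of str
        Ordered individual identifiers.
    snp_ids : list of str
        Ordered SNP identifiers (unique).
    dosage : ndarray of int8, shape (n_samples, n_snps)
        Count of the minor allele in {0, 1, 2}; ``-1`` is missing.
    alleles : list of (str, str)
        Per-SNP (major, minor) allele labels.
    chrom : ndarray of str
        Chromosome per SNP.
    pos : ndarray of int
        1-based base position per SNP, nondecreasing within a chromosome.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    alleles: list[tuple[str, str]]
    chrom: np.ndarray = field(default=None)
    pos: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")
        for major, minor in self.alleles:
            if major == minor:
                raise ValueError(f"major and minor allele identical: {major}")
        if self.chrom is None:
            self.chrom = np.array(["1"] * m, dtype=object)
        if self.pos is None:
            self.pos = np.arange(1, m + 1, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeTable":
        """Restrict to the given SNPs, preserving sample order."""
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            snp_ids=list(snp_ids),
            dosage=self.dosage[:, idx].copy(),
            alleles=[self.alleles[i] for i in idx],
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeTable(
            sample_ids=ids,
            snp_ids=list(self.snp_ids),
            dosage=self.dosage[mask].copy(),
            alleles=list(self.alleles),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
        )

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_hom_major, n_het, n_hom_minor) at SNP index ``j``, missing excluded."""
        col = self.dosage[:, j]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


@dataclass
class PhenotypeTable:
    """Case-control status plus the four stratification covariates."""

    frame: pd.DataFrame  # columns: sample_id, status, age, sex, smoking, drinking

    REQUIRED = ("sample_id", "status")
    COLUMNS = ("sample_id", "status", "age", "sex", "smoking", "drinking")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if self.frame["status"].isna().any():
            raise ValueError("status may not be missing")
        bad = set(self.frame["status"].unique()) - set(STATUS_LEVELS)
        if bad:
            raise ValueError(f"unknown status levels: {sorted(bad)}")
        for col in ("age", "sex", "smoking", "drinking"):
            if col not in self.frame.columns:
                self.frame[col] = np.nan
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def is_case(self) -> np.ndarray:
        return (self.frame["status"] == "case").to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def aligned_to(self, genotypes: GenotypeTable) -> "PhenotypeTable":
        """Reorder rows to match the genotype table's sample order."""
        frame = self.frame.set_index("sample_id")
        missing = [s for s in genotypes.sample_ids if s not in frame.index]
        if missing:
            raise ValueError(f"phenotypes missing for samples: {missing[:5]}")
        out = frame.loc[genotypes.sample_ids].reset_index()
        return PhenotypeTable(out)

    def subset(self, mask: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class VariantAnnotation:
    """Per-SNP QC annotations used by the variant filters."""

    frame: pd.DataFrame
    # columns: snp_id, hwe_p, dup_flag, depth, gap_distance, cnv_count

    def __post_init__(self) -> None:
        if "snp_id" not in self.frame.columns:
            raise ValueError("annotation table requires a snp_id column")
        if "hwe_p" in self.frame.columns:
            p = self.frame["hwe_p"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValueError("hwe_p outside [0,1]")
        for col, low in (("depth", 0), ("gap_distance", 0)):
            if col in self.frame.columns and (self.frame[col].dropna() < low).any():
                raise ValueError(f"{col} must be >= {low}")
        self.frame = self.frame.reset_index(drop=True)
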