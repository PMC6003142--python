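"""Readers and writers for PED/MAP, VCF and phenotype tables.

PED/MAP is the PLINK text dialect: one individual per PED row (six mandatory
columns followed by two allele columns per SNP) with SNP metadata in the MAP
file.  VCF is read through cyvcf2; biallelic records only.  All result tables
produced by the package are UTF-8, tab-separated, one header line.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EXPOSURE_LEVELS,
    MISSING,
    SEX_LEVELS,
    STATUS_LEVELS,
    FormatError,
    GenotypeTable,
    PhenotypeTable,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT0")


def read_ped_map(ped_path, map_path) -> GenotypeTable:
    """Read a PLINK text fileset into a dosage matrix.

    The minor allele is defined per dataset (pooled over all individuals) as
    the allele with the lower sample frequency; frequency ties are broken by
    lexical order (the lexically first allele is taken as major).  The "0 0"
    genotype is missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            map_rows.append(parts)
    snp_ids = [r[1] for r in map_rows]
    chrom = np.array([r[0] for r in map_rows], dtype=object)
    pos = np.array([int(r[3]) for r in map_rows], dtype=np.int64)
    m = len(snp_ids)

    sample_ids = []
    calls = []  # per sample: list of (a1, a2)
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns, got {len(parts)}"
                )
            for tok in parts[6:]:
                if tok not in _VALID_ALLELES:
                    raise FormatError(f"{ped_path}:{ln}: invalid allele symbol {tok!r}")
            sample_ids.append(parts[1])
            calls.append(list(zip(parts[6::2], parts[7::2])))

    n = len(sample_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    alleles = []
    for j in range(m):
        counts = Counter()
        for i in range(n):
            a1, a2 = calls[i][j]
            if a1 != "0" and a2 != "0":
                counts[a1] += 1
                counts[a2] += 1
        if len(counts) > 2:
            raise FormatError(f"SNP {snp_ids[j]} has >2 alleles: {sorted(counts)}")
        if not counts:
            alleles.append(("N", "N'"))
            continue
        obs = sorted(counts)  # lexical
        if len(obs) == 1:
            major, minor = obs[0], "N"
        else:
            a, b = obs
            if counts[a] == counts[b]:
                major, minor = a, b  # tie: lexically first is major
            elif counts[a] > counts[b]:
                major, minor = a, b
            else:
                major, minor = b, a
        alleles.append((major, minor))
        for i in range(n):
            a1, a2 = calls[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeTable(sample_ids, snp_ids, dosage, alleles, chrom, pos)


def write_ped_map(genotypes: GenotypeTable, ped_path, map_path,
                  phenotypes: PhenotypeTable | None = None) -> None:
    """Write a GenotypeTable as a PLINK text fileset (inverse of read_ped_map)."""
    with open(map_path, "w") as fh:
        for j, sid in enumerate(genotypes.snp_ids):
            fh.write(f"{genotypes.chrom[j]}\t{sid}\t0\t{genotypes.pos[j]}\n")
    status = {}
    if phenotypes is not None:
        status = dict(zip(phenotypes.sample_ids,
                          np.where(phenotypes.is_case, "2", "1")))
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            row = [sid, sid, "0", "0", "0", status.get(sid, "0")]
            for j, (major, minor) in enumerate(genotypes.alleles):
                d = genotypes.dosage[i, j]
                if d == MISSING:
                    row += ["0", "0"]
                else:
                    row += [minor if k < d else major for k in range(2)]
            fh.write("\t".join(row) + "\n")


def read_vcf(vcf_path) -> GenotypeTable:
    """Read a biallelic VCF into a dosage matrix (ALT = counted allele).

    Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multiallelic records are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    snp_ids, rows, alleles, chrom, pos = [], [], [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        if rec.format("GT") is None and rec.genotypes is None:
            raise FormatError(f"record {rec.ID or rec.POS} lacks a GT field")
        gt = rec.genotype.array()[:, :2]
        d = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1))
        rows.append(d.astype(np.int8))
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        alleles.append((rec.REF, rec.ALT[0]))
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
    if skipped:
        logger.warning("skipped %d multiallelic records in %s", skipped, vcf_path)
    dosage = np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), np.int8)
    return GenotypeTable(sample_ids, snp_ids, dosage,
                         alleles, np.array(chrom, object), np.array(pos))


def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a minimal VCF v4.2 (major allele as REF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, sid in enumerate(genotypes.snp_ids):
            major, minor = genotypes.alleles[j]
            cells = [code[int(d)] for d in genotypes.dosage[:, j]]
            fh.write(f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{sid}\t{major}\t{minor}"
                     "\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n")


_SEX_TOKENS = {"f": "female", "female": "female", "m": "male", "male": "male",
               "1": "male", "2": "female"}
_EXPOSURE_TOKENS = {"never": "never", "no": "never", "0": "never",
                    "ever": "ever", "current": "ever", "yes": "ever", "1": "ever"}
_STATUS_TOKENS = {"case": "case", "control": "control", "1": "case", "0": "control"}


def read_phenotypes(path, column_map: dict[str, str] | None = None,
                    sep: str | None = None) -> PhenotypeTable:
    """Read a phenotype CSV/TSV with a header line.

    ``column_map`` renames input columns onto the canonical names
    (sample_id, status, age, sex, smoking, drinking).  Categorical fields are
    normalized to the controlled vocabulary; unknown tokens become missing
    (the count is logged).  An absent status column is fatal.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.strip().lower() for c in df.columns]
    if "status" not in df.columns:
        raise FormatError(f"{path}: no status column")
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", [f"S{i}" for i in range(len(df))])
    df["sample_id"] = df["sample_id"].astype(str)

    unknown = 0
    def norm(col, tokens, levels):
        nonlocal unknown
        if col not in df.columns:
            df[col] = np.nan
            return
        vals = df[col].astype(str).str.strip().str.lower()
        mapped = vals.map(tokens)
        unknown += int((mapped.isna() & vals.notna() & ~vals.isin(["nan", ""])).sum())
        df[col] = pd.Categorical(mapped, categories=levels)

    norm("sex", _SEX_TOKENS, SEX_LEVELS)
    norm("smoking", _EXPOSURE_TOKENS, EXPOSURE_LEVELS)
    norm("drinking", _EXPOSURE_TOKENS, EXPOSURE_LEVELS)
    status = df["status"].astype(str).str.strip().str.lower().map(_STATUS_TOKENS)
    if status.isna().any():
        raise FormatError(f"{path}: unrecognized status tokens")
    df["status"] = status
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if unknown:
        logger.warning("%d unrecognized covariate tokens set to missing", unknown)
    return PhenotypeTable(df[[c for c in PhenotypeTable.COLUMNS if c in df.columns]])


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.frame.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> VariantAnnotation:
    """Read the variant-annotation TSV used by the QC filters."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return VariantAnnotation(df)


def write_annotations(annotations: VariantAnnotation, path) -> None:
    annotations.frame.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table: UTF-8, tab-separated, one header line."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
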