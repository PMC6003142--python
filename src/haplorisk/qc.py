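"""Variant QC: Hardy-Weinberg testing and the five-criterion SNP filter.

A SNP is removed when any of the following triggers: departure from
Hardy-Weinberg equilibrium (p < 1e-4), a duplicated-read flag, overall depth
<= 8x, position within 10 bp of an alignment gap, or an overlapping copy
number variant (>= 2 copies).  Boundary semantics are inclusive on the
failing side.  The duplicated-read criterion cannot be recomputed from
genotypes and is consumed as a precomputed flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .core import GenotypeTable, VariantAnnotation

logger = logging.getLogger(__name__)

CRITERIA = ("hwe", "duplicated_reads", "low_depth", "near_gap", "cnv")


@dataclass
class FilterThresholds:
    """Filter boundaries; defaults follow the inclusive-failure convention."""

    hwe_p: float = 1e-4          # fail if p < hwe_p
    max_depth_fail: float = 8.0  # fail if depth <= this
    gap_bp: float = 10.0         # fail if within this many bp of a gap
    cnv_min: int = 2             # fail if cnv_count >= this


@dataclass
class FilterReport:
    snp_id: str
    failed_criteria: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def _log_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """Log probability of n_het heterozygotes given rare-allele count and N
    genotypes, conditional on the allele counts (hypergeometric-type kernel)."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (
        gammaln(n + 1)
        - gammaln(n_het + 1) - gammaln(n_hom_rare + 1) - gammaln(n_hom_common + 1)
        + n_het * np.log(2.0)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int,
             method: str = "exact") -> float:
    """Two-sided Hardy-Weinberg equilibrium p-value from genotype counts.

    ``exact`` sums, conditional on the allele counts, the probabilities of
    every heterozygote count no more probable than the observed one.
    ``chisq`` is the 1-df Pearson test against HWE-expected counts.
    A monomorphic SNP returns p = 1 with a warning.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = n_het + 2 * n_hom_minor
    n_major = n_het + 2 * n_hom_major
    if n_minor == 0 or n_major == 0:
        logger.warning("monomorphic SNP: HWE p set to 1")
        return 1.0
    if method == "chisq":
        p_a = n_major / (2 * n)
        exp = np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2]) * n
        stat = float(((np.array(counts) - exp) ** 2 / exp).sum())
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    n_rare = min(n_minor, n_major)
    # heterozygote counts sharing the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[n_rare - hets <= 2 * (n - hets)]  # feasibility
    logp = np.array([_log_het_prob(int(h), n_rare, n) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_from_genotypes(genotypes: GenotypeTable, mask: np.ndarray | None = None,
                       method: str = "exact") -> np.ndarray:
    """HWE p per SNP, optionally restricted to a sample mask (e.g. controls)."""
    g = genotypes if mask is None else genotypes.subset_samples(mask)
    return np.array([hwe_test(*g.genotype_counts(j), method=method)
                     for j in range(g.n_snps)])


def apply_filters(annotations: VariantAnnotation,
                  thresholds: FilterThresholds | None = None) -> list[FilterReport]:
    """Evaluate the five filter criteria per SNP.

    A SNP fails when ANY criterion triggers; every triggered criterion is
    listed.  A missing annotation column skips that criterion with a warning.
    """
    th = thresholds or FilterThresholds()
    df = annotations.frame
    reports = []
    missing_cols = set()

    def col(name):
        if name in df.columns:
            return df[name]
        missing_cols.add(name)
        return None

    hwe_p = col("hwe_p")
    dup = col("dup_flag")
    depth = col("depth")
    gap = col("gap_distance")
    cnv = col("cnv_count")
    for i, snp_id in enumerate(df["snp_id"]):
        failed = []
        if hwe_p is not None and pd.notna(hwe_p.iat[i]) and hwe_p.iat[i] < th.hwe_p:
            failed.append("hwe")
        if dup is not None and bool(dup.iat[i]):
            failed.append("duplicated_reads")
        if depth is not None and pd.notna(depth.iat[i]) and depth.iat[i] <= th.max_depth_fail:
            failed.append("low_depth")
        if gap is not None and pd.notna(gap.iat[i]) and gap.iat[i] <= th.gap_bp:
            failed.append("near_gap")
        if cnv is not None and pd.notna(cnv.iat[i]) and cnv.iat[i] >= th.cnv_min:
            failed.append("cnv")
        reports.append(FilterReport(str(snp_id), tuple(failed)))
    if missing_cols:
        logger.warning("annotation columns absent, criteria skipped: %s",
                       sorted(missing_cols))
    return reports


def filter_genotypes(genotypes: GenotypeTable,
                     reports: list[FilterReport]) -> GenotypeTable:
    """Drop failing SNPs from a genotype table, preserving sample order."""
    passed = {r.snp_id for r in reports if r.passed}
    keep = [s for s in genotypes.snp_ids if s in passed]
    return genotypes.subset_snps(keep)


def report_frame(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snp_id": [r.snp_id for r in reports],
         "passed": [r.passed for r in reports],
         "failed_criteria": [",".join(r.failed_criteria) for r in reports]}
    )
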