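"""Case-control association statistics on 2x2 allele and haplotype tables.

The primary test is the uncorrected 1-df Pearson chi-square

    T = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]

on a table whose rows are case/control and whose columns count allele (or
haplotype) copies.  Fractional cell values are accepted without rounding,
because haplotype tables built from EM-expected copy numbers are fractional
by construction.  Covariate-adjusted odds ratios come from a logistic model
(status ~ copies + age + sex + smoking + drinking, complete cases), and
multiplicity is controlled by the Bonferroni rule alpha / m.  Stratified
analysis reruns the test within each level of a binary stratifier and
reports the between-stratum p-value ratio Pi = P2 / P1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .core import MISSING, GenotypeTable, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class TwoByTwoTable:
    """Counts: a = case exposed, b = case unexposed, c/d likewise controls.

    Cells are nonnegative reals; fractional values are legitimate for
    EM-expected haplotype counts.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("table cells must be nonnegative")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")


@dataclass
class AssociationResult:
    statistic: float
    p: float
    or_point: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    p_adjusted: float | None = None
    or_adjusted: float | None = None
    p_permutation: float | None = None


def chisq_2x2(table: TwoByTwoTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square and its 1-df upper-tail probability.

    A zero row or column margin is a degenerate table: T = 0, p = 1 with a
    warning.  No continuity correction is applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        logger.warning("degenerate 2x2 table (zero margin); T=0, p=1")
        return 0.0, 1.0
    t = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(t), float(chi2.sf(t, df=1))


def allele_table(genotypes: GenotypeTable, phenotypes: PhenotypeTable,
                 snp_id: str, count_minor: bool = False) -> TwoByTwoTable:
    """2x2 allele-copy table at one SNP; missing dosages are excluded.

    By default column 1 counts the major allele (printed-table convention:
    major first); ``count_minor`` flips the columns.
    """
    phen = phenotypes.aligned_to(genotypes)
    j = genotypes.snp_index(snp_id)
    dos = genotypes.dosage[:, j]
    ok = dos != MISSING
    if not ok.any():
        raise ValueError(f"SNP {snp_id}: all genotypes missing")
    case = phen.is_case
    minor_case = float(dos[ok & case].sum())
    minor_ctrl = float(dos[ok & ~case].sum())
    tot_case = 2.0 * int((ok & case).sum())
    tot_ctrl = 2.0 * int((ok & ~case).sum())
    if count_minor:
        return TwoByTwoTable(minor_case, tot_case - minor_case,
                             minor_ctrl, tot_ctrl - minor_ctrl)
    return TwoByTwoTable(tot_case - minor_case, minor_case,
                         tot_ctrl - minor_ctrl, minor_ctrl)


def haplotype_table(counts) -> TwoByTwoTable:
    """2x2 table from ExpectedHaplotypeCounts (target vs all others)."""
    return TwoByTwoTable(counts.case_count, counts.case_rest,
                         counts.control_count, counts.control_rest)


def crude_or(table: TwoByTwoTable) -> tuple[float, float, float]:
    """Unadjusted odds ratio with Woolf 95% CI.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells before computing the ratio and its interval.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.975)
    return (float(point), float(point * np.exp(-z * se)),
            float(point * np.exp(z * se)))


SEPARATION_BOUND = 15.0


def adjusted_association(exposure: np.ndarray, phenotypes: PhenotypeTable,
                         covariates: tuple[str, ...] = ("age", "sex",
                                                        "smoking", "drinking"),
                         ) -> tuple[float, float]:
    """Covariate-adjusted odds ratio and Wald p for a 0-2 copy exposure.

    Fits status ~ exposure + covariates by IRLS (age continuous; sex,
    smoking, drinking binary indicators), complete cases only.  Separation
    (|log OR| > 15) is flagged non-estimable with (nan, nan).
    """
    import statsmodels.api as sm

    frame = phenotypes.frame
    X = pd.DataFrame({"exposure": np.asarray(exposure, dtype=float)})
    for cov in covariates:
        col = frame[cov]
        if cov == "age":
            X[cov] = pd.to_numeric(col, errors="coerce")
        else:
            lab = {"sex": "male", "smoking": "ever", "drinking": "ever"}[cov]
            vals = col.astype(object)
            X[cov] = np.where(pd.isna(vals), np.nan,
                              (np.asarray(vals, dtype=object) == lab).astype(float))
    y = phenotypes.is_case.astype(float)
    complete = ~X.isna().any(axis=1).to_numpy()
    if complete.sum() < 10:
        raise ValueError("fewer than 10 complete-case samples")
    Xc = sm.add_constant(X.loc[complete], has_constant="add")
    try:
        fit = sm.Logit(y[complete], Xc).fit(disp=0, maxiter=200)
    except Exception:
        logger.warning("logistic fit failed; adjusted result non-estimable")
        return float("nan"), float("nan")
    beta = fit.params["exposure"]
    if abs(beta) > SEPARATION_BOUND:
        logger.warning("separation detected (|beta|=%.1f); non-estimable", abs(beta))
        return float("nan"), float("nan")
    return float(np.exp(beta)), float(fit.pvalues["exposure"])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


STRATUM_LEVELS = {
    "age": ("<=55", ">55"),
    "sex": ("female", "male"),
    "smoking": ("never", "ever"),
    "drinking": ("never", "ever"),
}


def stratify_mask(phenotypes: PhenotypeTable, variable: str,
                  age_cut: float = 55.0):
    """Yield (level_name, boolean mask) for the binary stratifier.

    Age dichotomizes at the cut (<=55 then >55); the categorical variables
    use their declared level order (never then ever; female then male).
    Missing covariate values fall in no stratum.
    """
    frame = phenotypes.frame
    if variable == "age":
        age = pd.to_numeric(frame["age"], errors="coerce")
        yield f"<={age_cut:g}", (age <= age_cut).to_numpy()
        yield f">{age_cut:g}", (age > age_cut).to_numpy()
    elif variable in STRATUM_LEVELS:
        vals = frame[variable].astype(object)
        for level in STRATUM_LEVELS[variable]:
            yield level, (np.asarray(vals, dtype=object) == level)
    else:
        raise ValueError(f"unknown stratum variable {variable!r}")


def pi_ratio(p1: float, p2: float) -> float:
    """Between-stratum p-value ratio Pi = P2 / P1 (stratum order declared)."""
    if p1 <= 0:
        raise ZeroDivisionError("first-stratum p is zero; Pi undefined")
    return p2 / p1


def stratified_analysis(exposure: np.ndarray, phenotypes: PhenotypeTable,
                        stratum_variable: str, age_cut: float = 55.0,
                        adjust: bool = False) -> pd.DataFrame:
    """Association within each stratum of a binary variable, plus Pi.

    ``exposure`` is a per-sample 0-2 copy count (fractional EM dosages
    allowed).  The chi-square runs on expected copy-count tables within
    each stratum; Pi = P2/P1 with the declared stratum order.  An empty
    stratum leaves its row and Pi as NaN with a warning.
    """
    exposure = np.asarray(exposure, dtype=float)
    rows = []
    pvals = []
    for level, mask in stratify_mask(phenotypes, stratum_variable, age_cut):
        ok = mask & ~np.isnan(exposure)
        if ok.sum() == 0:
            logger.warning("empty stratum %s=%s", stratum_variable, level)
            rows.append({"stratum": level, "n": 0, "chi2": np.nan, "p": np.nan})
            pvals.append(np.nan)
            continue
        case = phenotypes.is_case & ok
        ctrl = ~phenotypes.is_case & ok
        a = float(exposure[case].sum())
        c = float(exposure[ctrl].sum())
        tab = TwoByTwoTable(a, 2.0 * case.sum() - a, c, 2.0 * ctrl.sum() - c)
        t, p = chisq_2x2(tab)
        orr, lo, hi = crude_or(tab)
        row = {"stratum": level, "n": int(ok.sum()), "chi2": t, "p": p,
               "or": orr, "or_ci_low": lo, "or_ci_high": hi}
        if adjust:
            sub = phenotypes.subset(ok)
            covs = tuple(c for c in ("age", "sex", "smoking", "drinking")
                         if c != stratum_variable)
            try:
                or_adj, p_adj = adjusted_association(exposure[ok], sub, covs)
            except ValueError:
                or_adj, p_adj = np.nan, np.nan
            row.update({"or_adjusted": or_adj, "p_adjusted": p_adj})
        rows.append(row)
        pvals.append(p)
    out = pd.DataFrame(rows)
    out["pi_ratio"] = np.nan
    if len(pvals) == 2 and np.isfinite(pvals).all() and pvals[0] > 0:
        out.loc[1, "pi_ratio"] = pi_ratio(pvals[0], pvals[1])
    return out
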