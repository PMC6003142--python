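"""Q-Q diagnostics and false-positive report probability (FPRP).

The Q-Q comparison pairs sorted observed statistics with theoretical
quantiles at probability points (i - 0.5)/n, i = 1..n — the standard
plotting positions — under either a standard normal or a 1-df chi-square
reference.  FPRP is the posterior probability that a reported significant
association is false:

    FPRP = p (1 - pi) / [p (1 - pi) + power * pi]

where p is the observed test probability, pi the prior probability of a
true association, and power the probability of detecting a target odds
ratio (1.50 for risk, 0.67 for protection) at the study's sample sizes.
Power uses the normal approximation on the log-odds scale with the standard
error taken from the observed 2x2 table.  FPRP <= 0.2 is treated as
noteworthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .association import TwoByTwoTable


@dataclass
class QQPoints:
    expected: np.ndarray
    observed: np.ndarray
    reference: str

    def __post_init__(self) -> None:
        if len(self.expected) != len(self.observed):
            raise ValueError("expected and observed lengths differ")


@dataclass
class FPRPResult:
    p_observed: float
    power: float
    prior: float
    fprp: float

    #: FPRP at or below this is treated as a noteworthy association
    THRESHOLD = 0.2

    @property
    def significant(self) -> bool:
        return self.fprp <= self.THRESHOLD


def expected_quantiles(n: int, reference: str = "chisq1") -> np.ndarray:
    """Theoretical quantiles at plotting positions (i - 0.5)/n, i = 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    q = (np.arange(1, n + 1) - 0.5) / n
    if reference == "normal":
        return norm.ppf(q)
    if reference == "chisq1":
        return chi2.ppf(q, df=1)
    raise ValueError(f"unknown reference {reference!r}")


def qq_points(observed_stats, reference: str = "chisq1",
              drop: int | None = None) -> QQPoints:
    """Sorted observed statistics paired with reference quantiles.

    ``drop`` removes the given number of largest observed values before
    pairing (leave-one-out inspection of an outlying statistic).
    """
    obs = np.sort(np.asarray(observed_stats, dtype=float))
    if obs.size == 0:
        raise ValueError("no observed statistics")
    if drop:
        obs = obs[:-drop]
        if obs.size == 0:
            raise ValueError("all statistics dropped")
    return QQPoints(expected_quantiles(obs.size, reference), obs, reference)


def power_at_or(table: TwoByTwoTable, target_or: float = 1.5,
                alpha: float = 0.05) -> float:
    """Power to detect a target OR at the observed table's sample sizes.

    Normal approximation on the log-odds scale: the standard error of the
    log OR is sqrt(1/a + 1/b + 1/c + 1/d) from the observed table (with the
    +0.5 correction if any cell is zero); a protective target (< 1) uses
    |ln OR|.  alpha = 1 returns power 1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        return 1.0
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    sigma = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    delta = abs(np.log(target_or)) / sigma
    z = norm.ppf(1 - alpha / 2)
    return float(norm.sf(z - delta) + norm.cdf(-z - delta))


def fprp(p_observed: float, power: float, prior: float) -> FPRPResult:
    """False-positive report probability for one association."""
    for name, val in (("p_observed", p_observed), ("power", power),
                      ("prior", prior)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    num = p_observed * (1.0 - prior)
    den = num + power * prior
    value = 0.0 if prior == 1.0 else (1.0 if den == 0 else num / den)
    return FPRPResult(p_observed, power, prior, float(value))


def fprp_grid(analyses: dict[str, tuple[TwoByTwoTable, float]],
              priors=(0.1, 0.01, 0.001, 0.0001), target_or: float = 1.5,
              alpha: float | None = None):
    """FPRP over a prior grid for several analyses.

    ``analyses`` maps a row label to (observed table, observed p).  When
    ``alpha`` is None the power calculation uses the observed p as its
    significance level (Wacholder convention); otherwise the fixed alpha.
    Returns a pandas DataFrame with one row per analysis: the power column
    followed by one FPRP column per prior.
    """
    import pandas as pd

    rows = []
    for label, (table, p_obs) in analyses.items():
        a = p_obs if alpha is None else alpha
        pw = power_at_or(table, target_or=target_or, alpha=max(a, 1e-300))
        row = {"analysis": label, "p_observed": p_obs, "power": pw}
        for prior in priors:
            row[f"fprp_{prior:g}"] = fprp(p_obs, pw, prior).fprp
        rows.append(row)
    return pd.DataFrame(rows)
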