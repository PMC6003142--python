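"""Family-wise empirical p-values by label permutation with max(T).

Case/control labels are shuffled B times (preserving the case count); for
each shuffle the association statistic is recomputed for every marker and
only the maximum over markers is kept.  Each marker's empirical p compares
its observed statistic with that null max distribution, which controls the
family-wise error without assuming independence between markers.

The permuted statistic is the unadjusted chi-square on allele/haplotype
copy-count tables; exposures may be fractional EM dosages.  The default
counting rule r/B can report a floor of 1/B (e.g. 0.00001 at B = 1e5); the
conservative (r+1)/(B+1) estimator is available because r/B would otherwise
report zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .core import PhenotypeTable

_CHUNK = 2048  # permutations per matmul block


@dataclass
class PermutationResult:
    marker_ids: list[str]
    observed_T: np.ndarray
    p_empirical: np.ndarray          # max(T) family-wise p per marker
    p_single: np.ndarray             # per-marker (non-max) empirical p
    B: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _chisq_matrix(a, case_tot, minor_tot, grand_tot):
    """Vectorized 1-df Pearson chi-square for copy-count 2x2 tables.

    a = copies among cases; margins per marker (and permutation).  Zero
    margins give T = 0.
    """
    b = case_tot - a
    ctrl_tot = grand_tot - case_tot
    c = minor_tot - a
    d = ctrl_tot - c
    num = grand_tot * (a * d - b * c) ** 2
    den = case_tot * ctrl_tot * minor_tot * (grand_tot - minor_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return t


def _observed_stats(exposures, case):
    valid = ~np.isnan(exposures)
    e = np.nan_to_num(exposures)
    a = e @ case
    case_tot = 2.0 * (valid @ case)
    grand_tot = 2.0 * valid.sum(axis=1)
    minor_tot = e.sum(axis=1)
    return _chisq_matrix(a, case_tot, minor_tot, grand_tot)


def maxT(exposures: np.ndarray, phenotypes: PhenotypeTable | np.ndarray,
         B: int = 100_000, seed: int | None = 0,
         counting_rule: str = "paper", marker_ids: list[str] | None = None,
         exhaustive: bool = False, stat_function=None) -> PermutationResult:
    """max(T) permutation test over a marker set.

    Parameters
    ----------
    exposures : (n_markers, n_samples) array
        Per-sample allele or haplotype copy counts in [0, 2]; NaN = missing
        (that sample is excluded for that marker).
    phenotypes : PhenotypeTable or boolean case indicator
    B : int
        Number of label permutations (ignored in exhaustive mode).
    counting_rule : {'paper', 'conservative'}
        'paper': p = r/B floored at 1/B; 'conservative': (r+1)/(B+1).
    exhaustive : bool
        Enumerate every distinct case-label arrangement instead of sampling
        (feasible only for tiny cohorts); B becomes C(n, n_case).
    stat_function : callable, optional
        Override statistic: maps (exposure_row, case_bool) -> scalar with
        larger = more extreme.  The default is the vectorized chi-square.
    """
    exposures = np.atleast_2d(np.asarray(exposures, dtype=float))
    case = (phenotypes.is_case if isinstance(phenotypes, PhenotypeTable)
            else np.asarray(phenotypes)).astype(float)
    n = case.size
    n_case = int(case.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("constant phenotype: permutation undefined")
    m = exposures.shape[0]
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(m)]

    if stat_function is None:
        stat = lambda rows, labels: _observed_stats(rows, labels)  # noqa: E731
    else:
        stat = lambda rows, labels: np.array(  # noqa: E731
            [stat_function(row, labels.astype(bool)) for row in rows])

    t_obs = stat(exposures, case)

    if exhaustive:
        if comb(n, n_case) > 200_000:
            raise ValueError("exhaustive enumeration infeasible at this n")
        label_sets = []
        for idx in combinations(range(n), n_case):
            lab = np.zeros(n)
            lab[list(idx)] = 1.0
            label_sets.append(lab)
        perms = np.array(label_sets).T        # n x B
        B = perms.shape[1]
    else:
        rng = np.random.default_rng(seed)
        perms = None

    r_max = np.zeros(m)
    r_single = np.zeros(m)
    done = 0
    while done < B:
        k = min(_CHUNK, B - done)
        if exhaustive:
            block = perms[:, done:done + k]
        else:
            # top-n_case ranks of uniform draws = uniform label arrangement
            order = np.argpartition(rng.random((k, n)), n_case, axis=1)
            block = np.zeros((k, n))
            np.put_along_axis(block, order[:, :n_case], 1.0, axis=1)
            block = block.T
        if stat_function is None:
            valid = ~np.isnan(exposures)
            e = np.nan_to_num(exposures)
            a = e @ block                               # m x k
            case_tot = 2.0 * (valid @ block)
            grand_tot = 2.0 * valid.sum(axis=1, keepdims=True)
            minor_tot = e.sum(axis=1, keepdims=True)
            t_perm = _chisq_matrix(a, case_tot, minor_tot, grand_tot)
        else:
            t_perm = np.stack([stat(exposures, block[:, col])
                               for col in range(k)], axis=1)
        max_t = t_perm.max(axis=0)                      # k
        r_max += (max_t[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)
        r_single += (t_perm >= t_obs[:, None] - 1e-12).sum(axis=1)
        done += k

    if counting_rule == "paper":
        p_max = np.maximum(r_max / B, 1.0 / B)
        p_single = np.maximum(r_single / B, 1.0 / B)
    elif counting_rule == "conservative":
        p_max = (r_max + 1) / (B + 1)
        p_single = (r_single + 1) / (B + 1)
    else:
        raise ValueError(f"unknown counting rule {counting_rule!r}")
    return PermutationResult(list(marker_ids), t_obs, p_max, p_single, B, seed)
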