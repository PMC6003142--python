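"""Multifactor dimensionality reduction (MDR) for gene-environment search.

MDR collapses the contingency cells of a k-factor combination into a binary
high/low-risk attribute: a cell is high-risk when its case:control ratio
reaches the overall case:control ratio of the training data, and high-risk
predicts "case".  Every k-subset of factors is scored by cross-validated
prediction error; the subset selected most often across splits (the
cross-validation consistency, CVC) with the lowest average held-out error
is the best interaction model, and its significance comes from permuting
the case/control labels and re-running the whole search.

Prediction error is balanced (mean of the class-wise error rates) by
default, which is robust to case/control imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class FactorTable:
    """Per-sample categorical factors plus case/control status.

    ``factors`` holds small integer codes; every factor must show at least
    two levels.  Rows with a missing factor are excluded at construction.
    """

    factors: pd.DataFrame
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if len(self.factors) != len(self.is_case):
            raise ValueError("factors and status length mismatch")
        for col in self.factors.columns:
            if self.factors[col].nunique() < 2:
                raise ValueError(f"factor {col!r} has fewer than 2 levels")

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    @property
    def n(self) -> int:
        return len(self.is_case)


@dataclass
class MDRModel:
    factors: tuple[str, ...]
    cvc: int
    n_splits: int
    avg_prediction_error: float
    cell_labels: dict[tuple[int, ...], str] = field(default_factory=dict)
    p_permutation: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.cvc <= self.n_splits:
            raise ValueError("cvc out of range")


def build_factor_table(phenotypes: PhenotypeTable, hap_dosage: np.ndarray,
                       carrier_rule: str = "assigned", age_cut: float = 55.0,
                       assignments=None) -> FactorTable:
    """Factor table: drinking, haplotype carrier, age group, smoking, sex.

    The haplotype factor is carrier status (>= 1 copy).  ``carrier_rule``
    'assigned' uses hard phase assignments (pass them via ``assignments`` as
    a per-sample copy count with NaN for unassigned); 'dosage' thresholds
    the EM-expected copy number at 0.5.  Age dichotomizes at the cut.
    Samples missing any factor are dropped (count logged).
    """
    frame = phenotypes.frame
    if carrier_rule == "assigned" and assignments is not None:
        copies = np.asarray(assignments, dtype=float)
    else:
        copies = np.asarray(hap_dosage, dtype=float)
    carrier = np.where(np.isnan(copies), np.nan,
                       (copies >= (1.0 if carrier_rule == "assigned" else 0.5))
                       .astype(float))
    age = pd.to_numeric(frame["age"], errors="coerce")
    factors = pd.DataFrame({
        "drinking": frame["drinking"].astype(object).map({"never": 0, "ever": 1}),
        "hap_carrier": carrier,
        "age_group": np.where(age.isna(), np.nan, (age > age_cut).astype(float)),
        "smoking": frame["smoking"].astype(object).map({"never": 0, "ever": 1}),
        "sex": frame["sex"].astype(object).map({"female": 0, "male": 1}),
    })
    ok = ~factors.isna().any(axis=1).to_numpy()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropping %d samples with missing factors", dropped)
    return FactorTable(factors.loc[ok].astype(int).reset_index(drop=True),
                       phenotypes.is_case[ok])


def label_cells(table: FactorTable, subset: tuple[str, ...],
                threshold_ratio: float | None = None) -> dict[tuple[int, ...], str]:
    """High/low-risk label per multifactor cell on training data.

    A cell is 'high' iff its case:control ratio >= threshold (default: the
    training case:control ratio); empty cells are 'low'.
    """
    cols = [table.factors[f].to_numpy() for f in subset]
    case = table.is_case
    if threshold_ratio is None:
        n_ctrl = (~case).sum()
        threshold_ratio = case.sum() / n_ctrl if n_ctrl else np.inf
    labels: dict[tuple[int, ...], str] = {}
    cells = list(zip(*cols))
    for cell in set(cells):
        mask = np.array([c == cell for c in cells])
        n_case = int((case & mask).sum())
        n_ctrl = int((~case & mask).sum())
        if n_case + n_ctrl == 0:
            labels[cell] = "low"
        elif n_ctrl == 0:
            labels[cell] = "high" if n_case > 0 else "low"
        else:
            labels[cell] = "high" if n_case / n_ctrl >= threshold_ratio else "low"
    return labels


def _cell_codes(table: FactorTable, subset: tuple[str, ...]):
    """Mixed-radix cell index per sample for a factor subset."""
    idx = np.zeros(table.n, dtype=np.int64)
    n_cells = 1
    for f in subset:
        col = table.factors[f].to_numpy()
        levels = int(col.max()) + 1
        idx = idx * levels + col
        n_cells *= levels
    return idx, n_cells


def _fold_assignment(case: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Status-stratified fold labels; every fold keeps both classes."""
    folds = np.empty(case.size, dtype=np.int64)
    for cls in (True, False):
        idx = np.flatnonzero(case == cls)
        if idx.size < n_folds:
            raise ValueError("a fold would lose a status class; reduce folds")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _split_errors(table: FactorTable, subsets, n_splits: int, seed):
    """Balanced training and held-out error per (subset, split).

    Splits are 10-fold status-stratified CV repeated n_splits/10 times with
    reshuffling (n_splits not a multiple of 10 falls back to literal
    n_splits-fold CV).  Returns (train_errors, test_errors), each of shape
    (n_subsets, n_splits).
    """
    rng = np.random.default_rng(seed)
    if n_splits % 10 == 0 and n_splits >= 10:
        n_folds, n_repeats = 10, n_splits // 10
    else:
        n_folds, n_repeats = n_splits, 1
    case = table.is_case
    test_errors = np.zeros((len(subsets), n_splits))
    train_errors = np.zeros((len(subsets), n_splits))
    codes = [_cell_codes(table, s) for s in subsets]
    for rep in range(n_repeats):
        folds = _fold_assignment(case, n_folds, rng)
        cols = slice(rep * n_folds, (rep + 1) * n_folds)
        for si, (cell_idx, n_cells) in enumerate(codes):
            key = folds * n_cells + cell_idx
            hist_case = np.bincount(key[case], minlength=n_folds * n_cells
                                    ).reshape(n_folds, n_cells)
            hist_ctrl = np.bincount(key[~case], minlength=n_folds * n_cells
                                    ).reshape(n_folds, n_cells)
            tot_case = hist_case.sum(axis=0)
            tot_ctrl = hist_ctrl.sum(axis=0)
            train_case = tot_case[None, :] - hist_case          # folds x cells
            train_ctrl = tot_ctrl[None, :] - hist_ctrl
            tcase = train_case.sum(axis=1, keepdims=True)
            tctrl = train_ctrl.sum(axis=1, keepdims=True)
            # high-risk iff case:ctrl >= training ratio; empty cells low
            high = (train_case * tctrl >= train_ctrl * tcase) \
                & ((train_case + train_ctrl) > 0)
            miss_case = np.where(~high, hist_case, 0).sum(axis=1)
            fa_ctrl = np.where(high, hist_ctrl, 0).sum(axis=1)
            test_errors[si, cols] = 0.5 * (
                miss_case / hist_case.sum(axis=1)
                + fa_ctrl / hist_ctrl.sum(axis=1))
            miss_case_tr = np.where(~high, train_case, 0).sum(axis=1)
            fa_ctrl_tr = np.where(high, train_ctrl, 0).sum(axis=1)
            train_errors[si, cols] = 0.5 * (
                miss_case_tr / tcase[:, 0] + fa_ctrl_tr / tctrl[:, 0])
    return train_errors, test_errors


def mdr_search(table: FactorTable, k_max: int, n_splits: int = 100,
               seed: int | None = 0) -> dict[int, MDRModel]:
    """Exhaustive k-factor MDR search with cross-validation consistency.

    For each k in 1..k_max, every k-subset is trained by cell labeling on
    each split's training folds; the split-winner is the subset with the
    lowest balanced training error (the convention of the classical MDR
    program), and the held-out fold supplies its prediction error.  CVC is
    how often the modal subset wins; its average held-out error over all
    splits is the model's prediction error.  Returns the best model per k;
    the overall best is the entry with maximal CVC, ties broken by minimal
    error.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    names = table.factor_names
    if k_max > len(names):
        raise ValueError("k_max exceeds the number of factors")
    subsets = []
    k_of = []
    for k in range(1, k_max + 1):
        for s in combinations(names, k):
            subsets.append(s)
            k_of.append(k)
    train_err, test_err = _split_errors(table, subsets, n_splits, seed)
    k_of = np.array(k_of)
    best: dict[int, MDRModel] = {}
    for k in range(1, k_max + 1):
        rows = np.flatnonzero(k_of == k)
        winners = rows[np.argmin(train_err[rows], axis=0)]  # per split
        counts = np.bincount(winners, minlength=len(subsets))
        modal = int(np.argmax(counts))
        model = MDRModel(
            factors=subsets[modal],
            cvc=int(counts[modal]),
            n_splits=n_splits,
            avg_prediction_error=float(test_err[modal].mean()),
            cell_labels=label_cells(table, subsets[modal]),
        )
        best[k] = model
    return best


def best_model(models: dict[int, MDRModel]) -> MDRModel:
    """Overall winner: max CVC, ties broken by min average error."""
    return max(models.values(),
               key=lambda m: (m.cvc, -m.avg_prediction_error))


def mdr_permutation_p(table: FactorTable, k_max: int, B: int = 1000,
                      n_splits: int = 100, seed: int | None = 0) -> float:
    """Permutation p for the best MDR model's held-out accuracy.

    Status labels are permuted B times; the full search is re-run each time
    and the permuted best model's balanced accuracy (1 - error) recorded.
    p = proportion of permutations at least as accurate as observed; a zero
    count is conventionally reported as '< 1/B' (see format_permutation_p).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = 1.0 - best_model(mdr_search(table, k_max, n_splits, seed)
                                ).avg_prediction_error
    r = 0
    case = table.is_case
    for b in range(B):
        perm = rng.permutation(case)
        shuffled = FactorTable(table.factors, perm)
        acc = 1.0 - best_model(
            mdr_search(shuffled, k_max, n_splits, seed=rng.integers(2**31))
        ).avg_prediction_error
        if acc >= observed - 1e-12:
            r += 1
    return r / B


def format_permutation_p(p: float, B: int) -> str:
    """Render a permutation p, flooring an observed zero at '< 1/B'."""
    return f"< {1.0 / B:g}" if p == 0 else f"{p:g}"


def report_frame(models: dict[int, MDRModel]) -> pd.DataFrame:
    rows = []
    for k in sorted(models):
        m = models[k]
        rows.append({"k": k, "model": ",".join(m.factors),
                     "cvc": f"{m.cvc}/{m.n_splits}",
                     "avg_prediction_error": m.avg_prediction_error,
                     "p_permutation": m.p_permutation})
    return pd.DataFrame(rows)
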