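"""Diagnostic-performance evaluation of the subspace classifier.

Implements ROC/AUC from decision values, stratified 10-fold and nested
cross-validation with subspace-dimension tuning, learning curves over
stratified subset sizes with repetitions, and a one-tailed t-test of the
repetition AUCs against chance (AUC 0.5) preceded by an Anderson--Darling
normality check.

Conventions
-----------
The bleeding class is the positive class.  The classifier's decision value
is distance-to-bleeding minus distance-to-healthy, so *negative* values
favor bleeding; ROC scores are the negated decision values (higher = more
bleeding-like).  All randomness flows through a caller-supplied
``numpy.random.Generator``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .classifier import residuals_by_dimension
from .records import BLEEDING, TransmissionRecord
from .classifier import vectorize

__all__ = [
    "ROCCurve",
    "NestedCVResult",
    "LearningCurveResult",
    "stack_records",
    "roc_auc",
    "mann_whitney_auc",
    "kfold_cv",
    "nested_cv",
    "learning_curve",
    "test_vs_chance",
    "default_dimension_grid",
]

DEFAULT_SUBSET_SIZES = (30, 40, 50, 60, 100, 200, 300, 500, 750, 1000)


def default_dimension_grid(n_train_per_class: int) -> list[int]:
    """Tuning grid for the subspace dimension, capped at t_c - 1."""
    cap = max(1, n_train_per_class - 1)
    grid = sorted({min(d, cap) for d in (1, 2, 3, 5, 8, 12, 20)})
    return grid


def stack_records(records: list[TransmissionRecord]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into feature columns X (n_features, n) and labels y.

    ``y`` is 1 for bleeding, 0 for healthy.
    """
    X = np.column_stack([vectorize(r) for r in records])
    y = np.array([1 if r.label == BLEEDING else 0 for r in records])
    return X, y


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Offset-sweep ROC: thresholds with sensitivity/specificity and AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC by sweeping an offset over the decision values.

    ``scores``: higher favors the positive class.  A sample is called
    positive when ``score > threshold``; sweeping the threshold from above
    the largest score down to below the smallest traces the curve.  The
    trapezoidal area equals the Mann--Whitney probability of correct
    ranking with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])[::-1]
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, t in enumerate(thresholds):
        called_pos = scores > t
        sens[k] = np.sum(called_pos & (labels == 1)) / n_pos
        spec[k] = np.sum(~called_pos & (labels == 0)) / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann--Whitney statistic: P(score_pos > score_neg) + ties/2.

    Independent of :func:`roc_auc`; the two are cross-checked in tests.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # rank-based computation, O(n log n)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified k-fold partition; returns test-index arrays."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} subjects, fewer than k={k}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _fold_decisions(X: np.ndarray, y: np.ndarray, train: np.ndarray,
                    test: np.ndarray, dims: list[int]) -> np.ndarray:
    """Decision values on a test fold for every dimension in ``dims``.

    One thin SVD per class at the largest dimension; truncations give the
    whole grid.  Returns (len(dims), len(test)).
    """
    d_max = max(dims)
    out = np.empty((len(dims), test.size))
    resid = {}
    for cls in (1, 0):
        cols = train[y[train] == cls]
        u, _, _ = np.linalg.svd(X[:, cols], full_matrices=False)
        resid[cls] = residuals_by_dimension(u[:, :d_max], X[:, test])
    for k, d in enumerate(dims):
        out[k] = resid[1][d - 1] - resid[0][d - 1]  # bleed minus healthy
    return out


def kfold_cv(X: np.ndarray, y: np.ndarray, d: int, k: int = 10,
             rng: np.random.Generator | None = None
             ) -> tuple[np.ndarray, ROCCurve]:
    """Stratified k-fold CV at a fixed subspace dimension.

    Every subject is tested exactly once by a model never trained on it.
    Returns the per-subject decision values (in dataset order) and the
    pooled ROC.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y).astype(int)
    decisions = np.empty(y.size)
    all_idx = np.arange(y.size)
    for test in _stratified_folds(y, k, rng):
        train = np.setdiff1d(all_idx, test)
        decisions[test] = _fold_decisions(X, y, train, test, [d])[0]
    return decisions, roc_auc(-decisions, y)


@dataclass
class NestedCVResult:
    decisions: np.ndarray
    roc: ROCCurve
    chosen_dimensions: list[int]
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc


def nested_cv(X: np.ndarray, y: np.ndarray, dim_grid=None,
              k_outer: int = 10, k_inner: int = 10,
              rng: np.random.Generator | None = None) -> NestedCVResult:
    """Nested cross-validation with inner-loop subspace-dimension tuning.

    For each outer fold an inner stratified CV over the outer training set
    selects the grid dimension maximizing the pooled inner AUC (ties go to
    the smallest dimension); the outer test predictions of all folds are
    pooled into one ROC, so no subject ever influences its own tuning.
    Grid entries exceeding the inner training size are skipped with a
    warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y).astype(int)
    all_idx = np.arange(y.size)
    outer_folds = _stratified_folds(y, k_outer, rng)
    decisions = np.empty(y.size)
    chosen = []
    fold_aucs = []
    for test in outer_folds:
        train = np.setdiff1d(all_idx, test)
        y_tr = y[train]
        min_class = min(np.sum(y_tr == 1), np.sum(y_tr == 0))
        grid = dim_grid if dim_grid is not None else \
            default_dimension_grid(min_class)
        # inner loop: smallest class size within an inner training split
        inner_cap = min_class - int(np.ceil(min_class / k_inner))
        dims = [d for d in grid if d <= max(inner_cap, 1)]
        skipped = [d for d in grid if d not in dims]
        if skipped:
            warnings.warn(f"dimensions {skipped} exceed inner training size; "
                          "skipped", stacklevel=2)
        if not dims:
            raise ValueError("no feasible dimension in the tuning grid")
        inner_dec = np.empty((len(dims), train.size))
        inner_folds = _stratified_folds(y_tr, k_inner, rng)
        for inner_test_local in inner_folds:
            inner_train_local = np.setdiff1d(np.arange(train.size),
                                             inner_test_local)
            inner_dec[:, inner_test_local] = _fold_decisions(
                X, y, train[inner_train_local], train[inner_test_local], dims)
        inner_aucs = [mann_whitney_auc(-inner_dec[k], y_tr)
                      for k in range(len(dims))]
        best = dims[int(np.argmax(inner_aucs))]  # argmax ties -> first=smallest
        chosen.append(best)
        dec = _fold_decisions(X, y, train, test, [best])[0]
        decisions[test] = dec
        fold_aucs.append(mann_whitney_auc(-dec, y[test]))
    return NestedCVResult(decisions=decisions,
                          roc=roc_auc(-decisions, y),
                          chosen_dimensions=chosen,
                          fold_aucs=fold_aucs)


# ---------------------------------------------------------------------------
# Learning curve and significance vs chance
# ---------------------------------------------------------------------------

def test_vs_chance(aucs) -> tuple[float, float]:
    """Normality check and one-tailed t-test of repetition AUCs vs 0.5.

    Returns ``(anderson_darling_p, one_tailed_t_p)`` where the t-test is the
    one-sample test of the mean against 0.5 with alternative mean > 0.5.
    With zero variance the t statistic is undefined; the p-value is then 0,
    1, or 0.5 according to the sign of mean - 0.5, with a warning.
    """
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 3:
        raise ValueError("need at least 3 AUC values")
    if np.ptp(aucs) == 0.0:
        warnings.warn("zero variance in AUCs; t-test degenerate",
                      stacklevel=2)
        mean = aucs.mean()
        p = 0.0 if mean > 0.5 else (1.0 if mean < 0.5 else 0.5)
        return float("nan"), p
    ad_stat, ad_p = normal_ad(aucs)
    t_res = stats.ttest_1samp(aucs, 0.5, alternative="greater")
    return float(ad_p), float(t_res.pvalue)


@dataclass
class LearningCurveResult:
    """Per-subset-size repetition AUCs with summary statistics."""

    sizes: list[int]
    aucs: dict[int, list[float]]
    chosen_dimensions: dict[int, list[list[int]]] = field(default_factory=dict)

    @property
    def mean(self) -> dict[int, float]:
        return {n: float(np.mean(v)) for n, v in self.aucs.items()}

    @property
    def sd(self) -> dict[int, float]:
        return {n: float(np.std(v, ddof=1)) for n, v in self.aucs.items()}

    def significance(self) -> dict[int, tuple[float, float]]:
        """(Anderson-Darling p, one-tailed t p vs 0.5) per subset size."""
        return {n: test_vs_chance(v) for n, v in self.aucs.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for n in self.sizes:
            for rep, auc in enumerate(self.aucs[n]):
                rows.append({"size": n, "repeat": rep, "auc": auc})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        sig = self.significance()
        return pd.DataFrame([
            {"size": n, "mean_auc": self.mean[n], "sd_auc": self.sd[n],
             "normality_p": sig[n][0], "t_p": sig[n][1]}
            for n in self.sizes])


def learning_curve(X: np.ndarray, y: np.ndarray,
                   sizes=DEFAULT_SUBSET_SIZES, repeats: int = 10,
                   rng: np.random.Generator | None = None,
                   dim_grid=None, k_outer: int = 10, k_inner: int = 10
                   ) -> LearningCurveResult:
    """AUC as a function of stratified training-subset size.

    For every size and repetition an independent stratified random subset
    (half bleeding, half healthy) is drawn from the pool and evaluated with
    nested CV; the per-size mean and standard deviation over the
    repetitions, together with the normality and t-test p-values, form the
    learning curve.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y).astype(int)
    sizes = [int(n) for n in sizes]
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if max(sizes) > y.size:
        raise ValueError(f"largest size {max(sizes)} exceeds pool {y.size}")
    result = LearningCurveResult(sizes=sizes, aucs={n: [] for n in sizes},
                                 chosen_dimensions={n: [] for n in sizes})
    for n in sizes:
        half = n // 2
        if half > min(pos.size, neg.size):
            raise ValueError(f"size {n} needs {half} per class")
        for _ in range(repeats):
            sub = np.concatenate([
                rng.choice(pos, size=half, replace=False),
                rng.choice(neg, size=half, replace=False)])
            res = nested_cv(X[:, sub], y[sub], dim_grid=dim_grid,
                            k_outer=k_outer, k_inner=k_inner, rng=rng)
            result.aucs[n].append(res.auc)
            result.chosen_dimensions[n].append(res.chosen_dimensions)
    return result
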