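"""Evaluation metrics for imbalanced binary disturbance classification.

Implements the confusion-matrix statistics used throughout the package:
accuracy, precision, recall, F1, Conditional Kappa and the True Skill
Statistic, plus the Gleichlaeufigkeit sign-agreement score for annual
time series, max-F1 threshold calibration, and an algebraic back-solver
that recovers an integer confusion matrix from (N, accuracy, precision,
recall).

Note on formulas
----------------
Conditional Kappa and the True Skill Statistic are computed here as

    CK  = (precision - (tp+fn)/N) / (1 - (tp+fn)/N)
    TSS = precision + tn/(tn+fn) - 1

i.e. TSS is precision + negative-predictive-value - 1. The classical
definition of TSS in the ecology literature is sensitivity +
specificity - 1; that form is also reported (``tss_conventional``), as
is Cohen's-style kappa conditioned the usual way. The primary fields
follow the formulation this pipeline is built around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metric_report",
    "backsolve_confusion",
    "select_threshold",
    "gleichlaeufigkeit",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with 'disturbed' (attacked) as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion matrix is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        """Observed positives tp + fn."""
        return self.tp + self.fn

    @property
    def prevalence(self) -> float:
        return self.positives / self.n


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    conditional_kappa: float
    true_skill_statistic: float
    # conventional alternatives, not used by the headline evaluation
    tss_conventional: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float) -> float:
    """Division that flags undefined ratios as NaN instead of raising."""
    return num / den if den != 0 else math.nan


def confusion(labels, binary_predictions) -> ConfusionMatrix:
    """Cross-tabulate binary labels against binary predictions.

    Raises
    ------
    ValueError
        if lengths differ or values are not in {0, 1}.
    """
    y = np.asarray(labels).ravel()
    p = np.asarray(binary_predictions).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} labels vs {p.shape[0]} predictions")
    for name, a in (("labels", y), ("predictions", p)):
        if not np.isin(a, (0, 1)).all():
            bad = np.unique(a[~np.isin(a, (0, 1))])
            raise ValueError(f"{name} contain non-binary values {bad}")
    y = y.astype(bool)
    p = p.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(y & p)),
        tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
    )


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """Compute the six evaluation statistics from a confusion matrix.

    All arithmetic is double precision. Ratios with zero denominators
    (e.g. recall on a year with no observed attacks) are returned as
    NaN rather than raising.
    """
    tp, tn, fp, fn = (float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn))
    n = tp + tn + fp + fn
    accuracy = _ratio(tn + tp, n)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    pos_rate = (tp + fn) / n
    conditional_kappa = _ratio(precision - pos_rate, 1.0 - pos_rate)
    npv = _ratio(tn, tn + fn)
    tss = precision + npv - 1.0
    specificity = _ratio(tn, tn + fp)
    tss_conv = recall + specificity - 1.0
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        conditional_kappa=conditional_kappa,
        true_skill_statistic=tss,
        tss_conventional=tss_conv,
        n=int(n),
    )


def backsolve_confusion(
    n: int, accuracy: float, precision: float, recall: float, tol: float = 1e-3
) -> ConfusionMatrix:
    """Recover the integer confusion matrix from N, accuracy, precision, recall.

    The three rates plus the total determine the four counts. Writing
    P = tp + fn for the observed positives:

        errors = fp + fn = N (1 - accuracy)
        fn = P (1 - recall)
        fp = tp (1 - precision)/precision = P recall (1 - precision)/precision

    so ``P = N (1 - accuracy) / ((1 - recall) + recall (1 - precision)/precision)``.
    Counts are rounded to the nearest integers (tn as remainder) and the
    forward metrics are verified to reproduce the inputs within ``tol``.

    Raises
    ------
    ValueError
        if no consistent non-negative integer solution exists within ``tol``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= accuracy <= 1 and 0 < precision <= 1 and 0 <= recall <= 1):
        raise ValueError("rates must lie in [0, 1] (precision > 0)")
    denom = (1.0 - recall) + recall * (1.0 - precision) / precision
    if denom == 0.0:
        # precision = recall = 1: an error-free classifier. The rates no
        # longer pin down prevalence, so split the total evenly by
        # convention; fp = fn = 0 regardless.
        if accuracy != 1.0:
            raise ValueError("inconsistent inputs: accuracy < 1 with perfect precision/recall")
        tp = n // 2
        return ConfusionMatrix(tp=tp, tn=n - tp, fp=0, fn=0)
    positives = n * (1.0 - accuracy) / denom
    tp = int(round(positives * recall))
    fn = int(round(positives * (1.0 - recall)))
    fp = int(round(tp * (1.0 - precision) / precision))
    tn = n - tp - fn - fp
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("no non-negative solution")
    cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
    rep = metric_report(cm)
    checks = (
        (rep.accuracy, accuracy),
        (rep.precision, precision),
        (rep.recall, recall),
    )
    for got, want in checks:
        if math.isnan(got) or abs(got - want) > tol:
            raise ValueError(
                f"back-solved matrix {cm} reproduces metrics only to "
                f"|{got:.6f} - {want:.6f}| > {tol}"
            )
    return cm


def select_threshold(probabilities, labels, step: float = 0.001) -> float:
    """Probability cutoff maximizing F1 of (p >= threshold) on a fixed grid.

    The grid runs from 0 to 1 inclusive in increments of ``step``; ties
    are broken toward the larger threshold (the more conservative map).

    Raises
    ------
    ValueError
        if only one class is present in ``labels``.
    """
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if y.shape != p.shape:
        raise ValueError("probabilities and labels differ in length")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("threshold calibration needs both classes present")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    # positives with probability >= t, for every grid threshold t
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 12)
    idx = np.searchsorted(p_sorted, grid, side="left")
    pos_cum = np.concatenate(([0], np.cumsum(y_sorted)))  # positives below index
    tp = n_pos - pos_cum[idx]
    pred_pos = p.size - idx
    fp = pred_pos - tp
    fn = n_pos - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    f1 = np.nan_to_num(f1, nan=-1.0)
    best = np.flatnonzero(f1 >= f1.max() - 1e-15)[-1]  # largest threshold wins ties
    return float(grid[best])


def gleichlaeufigkeit(x, y) -> float:
    """Sign-agreement similarity of two equally long time series.

    Each year-over-year step of each series scores +1/2, 0 or -1/2 for a
    positive, zero or negative difference; the statistic is the mean of
    ``|G_i(x) + G_i(y)|`` over the n-1 steps. 1 means every step moves in
    the same (nonzero) direction in both series, 0 means every step moves
    in opposite directions.

    Symmetric in its arguments and invariant to adding a constant to
    either series.
    """
    xv = np.asarray(x, dtype=np.float64).ravel()
    yv = np.asarray(y, dtype=np.float64).ravel()
    if xv.shape != yv.shape:
        raise ValueError("series differ in length")
    if xv.size < 2:
        raise ValueError("need at least two time points")
    gx = 0.5 * np.sign(np.diff(xv))
    gy = 0.5 * np.sign(np.diff(yv))
    return float(np.mean(np.abs(gx + gy)))
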