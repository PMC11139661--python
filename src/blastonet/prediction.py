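"""Threshold classifier, exhaustive AUC-maximizing calibration, stratified
k-fold cross-validation, and between-model AUC comparison.

The classifier predicts a positive outcome when the feature exceeds a
cut-off theta.  Because the fitted model is a hard classifier, its AUC is
the rank-AUC of a two-level score, which equals (sensitivity +
specificity) / 2; the continuous-feature AUC is also reported per fold as
an auxiliary quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidParameterError,
)
from .stats import TTestResult, pooled_t_test

__all__ = [
    "ThresholdModel",
    "BinaryMetrics",
    "CVReport",
    "FoldResult",
    "fit_threshold",
    "binary_metrics",
    "cross_validate",
    "compare_models",
    "candidate_thresholds",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Predict positive when ``feature > theta``."""

    feature_name: str
    theta: float

    def predict(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) > self.theta).astype(int)


class BinaryMetrics(NamedTuple):
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    auc: float


def _check_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr).astype(int)
    if a.ndim != 1 or not np.isin(a, (0, 1)).all():
        raise InvalidParameterError(f"{name} must be a 1-d 0/1 array")
    return a


def binary_metrics(y_pred, y_true) -> BinaryMetrics:
    """Confusion-matrix metrics of a hard classifier.

    AUC is the rank statistic of the binary prediction, identically
    (sensitivity + specificity) / 2.  Precision is 0 when nothing is
    predicted positive; F1 is 0 when precision + sensitivity is 0.
    """
    y_pred = _check_binary(y_pred, "y_pred")
    y_true = _check_binary(y_true, "y_true")
    if len(y_pred) != len(y_true):
        raise InvalidParameterError("y_pred and y_true must have the same length")
    if y_true.min() == y_true.max():
        raise DegenerateLabelsError("y_true must contain both classes for AUC")

    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))

    accuracy = (tp + tn) / len(y_true)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    auc = (sensitivity + specificity) / 2.0
    return BinaryMetrics(accuracy, precision, sensitivity, f1, auc)


def candidate_thresholds(x) -> np.ndarray:
    """Exhaustive cut-off candidates for rank metrics: midpoints of
    consecutive distinct feature values, one below the minimum and one above
    the maximum.  Any finer grid yields the same set of predictions."""
    xs = np.unique(np.asarray(x, dtype=float))
    span = max(float(xs[-1] - xs[0]), 1.0)
    below = xs[0] - 0.5 * span
    above = xs[-1] + 0.5 * span
    mids = (xs[:-1] + xs[1:]) / 2.0
    return np.concatenate([[below], mids, [above]])


def fit_threshold(x, y, feature_name: str = "feature") -> ThresholdModel:
    """Exhaustive search over candidate thresholds maximizing the
    prediction-AUC of ``x > theta`` against ``y``; ties broken toward the
    smallest optimal theta."""
    x = np.asarray(x, dtype=float)
    y = _check_binary(y, "y")
    if len(x) != len(y):
        raise InvalidParameterError("x and y must have the same length")
    if y.min() == y.max():
        raise DegenerateLabelsError("labels contain a single class")

    thetas = candidate_thresholds(x)
    preds = x[None, :] > thetas[:, None]
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    tp = (preds & pos[None, :]).sum(axis=1)
    fp = (preds & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    auc = (sens + spec) / 2.0
    best = np.flatnonzero(auc == auc.max())[0]  # thetas ascending -> smallest
    return ThresholdModel(feature_name=feature_name, theta=float(thetas[best]))


@dataclass(frozen=True)
class FoldResult:
    fold: int
    theta: float
    metrics: BinaryMetrics | None  # None when test fold had a single class
    auc_continuous: float | None
    n_test: int
    flagged: bool = False


@dataclass(frozen=True)
class CVReport:
    outcome_name: str
    feature_name: str
    k: int
    seed: int
    folds: tuple
    summary: dict = field(default_factory=dict)
    theta_mean: float = float("nan")
    theta_sd: float = float("nan")

    @property
    def fold_aucs(self) -> list[float]:
        return [f.metrics.auc for f in self.folds if f.metrics is not None]


_METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "auc")


def cross_validate(
    x,
    y,
    k: int = 5,
    seed: int = 0,
    feature_name: str = "feature",
    outcome_name: str = "outcome",
) -> CVReport:
    """Stratified, shuffled, seeded k-fold evaluation of the threshold
    classifier.  Per fold: fit on the training folds, score on the held-out
    fold.  A test fold with single-class truth gets its AUC flagged missing.
    """
    x = np.asarray(x, dtype=float)
    y = _check_binary(y, "y")
    if len(x) != len(y):
        raise InvalidParameterError("x and y must have the same length")
    if len(x) < k:
        raise InvalidParameterError(f"need at least k={k} samples")
    if y.min() == y.max():
        raise DegenerateLabelsError("labels contain a single class")
    if min(int((y == 0).sum()), int((y == 1).sum())) < k:
        raise InvalidParameterError(
            f"each class needs >= k={k} members for stratified folds"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_idx, (train, test) in enumerate(skf.split(x.reshape(-1, 1), y)):
        model = fit_threshold(x[train], y[train], feature_name=feature_name)
        y_test = y[test]
        if y_test.min() == y_test.max():
            folds.append(
                FoldResult(
                    fold=fold_idx,
                    theta=model.theta,
                    metrics=None,
                    auc_continuous=None,
                    n_test=len(test),
                    flagged=True,
                )
            )
            continue
        m = binary_metrics(model.predict(x[test]), y_test)
        auc_cont = float(roc_auc_score(y_test, x[test]))
        folds.append(
            FoldResult(
                fold=fold_idx,
                theta=model.theta,
                metrics=m,
                auc_continuous=auc_cont,
                n_test=len(test),
            )
        )

    summary = {}
    for name in _METRIC_NAMES:
        vals = [getattr(f.metrics, name) for f in folds if f.metrics is not None]
        summary[name] = (
            float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        )
    thetas = [f.theta for f in folds]
    return CVReport(
        outcome_name=outcome_name,
        feature_name=feature_name,
        k=k,
        seed=seed,
        folds=tuple(folds),
        summary=summary,
        theta_mean=float(np.mean(thetas)),
        theta_sd=float(np.std(thetas, ddof=1)) if len(thetas) > 1 else float("nan"),
    )


def compare_models(report_a: CVReport, report_b: CVReport) -> TTestResult:
    """Unpaired pooled t-test on the two per-fold AUC samples."""
    a = report_a.fold_aucs
    b = report_b.fold_aucs
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each report needs >= 2 folds with defined AUC")
    return pooled_t_test(a, b)
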