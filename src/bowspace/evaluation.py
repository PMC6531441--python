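"""Confusion-matrix metrics, ROC curves, AUC, and cross-validated reports.

Metric definitions:

    Accuracy    = (TP + TN) / (TP + FP + TN + FN)
    Sensitivity = TP / (TP + FN)        (NaN when no positives were evaluated)
    Specificity = TN / (TN + FP)        (NaN when no negatives were evaluated)

The ROC curve is built by sweeping the decision threshold over the unique
scores in descending order (one vertex per unique score, so tied scores are
grouped), starting at (0, 0) and ending at (1, 1); AUC is its trapezoidal
area, which equals the Wilcoxon-Mann-Whitney rank statistic with ties
counted one half.

Cross-validation pools the out-of-fold scores for a single "average" ROC by
default; vertical threshold-averaging across folds is available as an
option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from bowspace.classifiers import ClassifierSpec, classify, predict_proba, train
from bowspace.exceptions import InvalidInputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metrics for one evaluation run (optionally with a per-fold breakdown)."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: np.ndarray  # (n_points, 2) columns FPR, TPR
    confusion: ConfusionMatrix
    per_fold: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _num(x):
            return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x

        return {
            "accuracy": _num(self.accuracy),
            "sensitivity": _num(self.sensitivity),
            "specificity": _num(self.specificity),
            "auc": _num(self.auc),
            "confusion": {"tp": self.confusion.tp, "tn": self.confusion.tn,
                          "fp": self.confusion.fp, "fn": self.confusion.fn},
            "roc": self.roc.tolist(),
            "per_fold": self.per_fold,
            "manifest": self.manifest,
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Standard confusion-cell counts for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise InvalidInputError("cannot build a confusion matrix from no pairs")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios are NaN, not 0."""
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    specificity = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC vertices (FPR, TPR) and trapezoidal AUC from a threshold sweep."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise InvalidInputError("y_true and scores must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC is undefined when only one class is present")

    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    # group ties: keep the last index of each unique-score run
    last_of_run = np.r_[np.nonzero(np.diff(s_sorted))[0], y_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[last_of_run]
    fps = np.cumsum(y_sorted == 0)[last_of_run]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return roc, auc


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report from true labels and probabilistic scores."""
    roc, auc = roc_auc(y_true, scores)
    cm = confusion(y_true, classify(scores, threshold))
    accuracy, sensitivity, specificity = metrics(cm)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, auc=auc, roc=roc, confusion=cm)


def vertical_average_roc(rocs, grid_size: int = 101) -> np.ndarray:
    """Threshold-averaged ROC: mean TPR over folds on a common FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = [np.interp(grid, roc[:, 0], roc[:, 1]) for roc in rocs]
    return np.column_stack([grid, np.mean(tprs, axis=0)])


def crossval_report(spec: ClassifierSpec, X, y, folds, threshold: float = 0.5,
                    average: str = "pooled") -> MetricsReport:
    """Cross-validated metrics for one classifier spec.

    Fits one model per fold, scores its test fold, and reports per-fold
    metrics plus a pooled out-of-fold ROC/AUC (``average="pooled"``) or a
    vertically threshold-averaged ROC (``average="vertical"``; AUC is then
    the area under the averaged curve).
    """
    if average not in ("pooled", "vertical"):
        raise InvalidInputError(f"unknown ROC averaging mode {average!r}")
    import pandas as pd

    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    pooled_scores = np.full(n, np.nan)
    per_fold = []
    fold_rocs = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        train_idx = np.asarray(train_idx, dtype=int)
        test_idx = np.asarray(test_idx, dtype=int)
        for idx in (train_idx, test_idx):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise InvalidInputError(f"fold {fold_id} references missing rows")
        X_tr = X.iloc[train_idx] if isinstance(X, pd.DataFrame) else X[train_idx]
        X_te = X.iloc[test_idx] if isinstance(X, pd.DataFrame) else X[test_idx]
        model = train(spec, X_tr, y[train_idx])
        scores = predict_proba(model, X_te).proba
        pooled_scores[test_idx] = scores
        report = evaluate_predictions(y[test_idx], scores, threshold)
        fold_rocs.append(report.roc)
        per_fold.append({
            "fold": fold_id,
            "n_test": int(test_idx.size),
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "auc": report.auc,
        })

    evaluated = ~np.isnan(pooled_scores)
    pooled = evaluate_predictions(y[evaluated], pooled_scores[evaluated], threshold)
    if average == "vertical":
        roc = vertical_average_roc(fold_rocs)
        auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
        pooled.roc, pooled.auc = roc, auc
    pooled.per_fold = per_fold
    pooled.manifest = {
        "classifier": spec.name,
        "params": spec.resolved_params(),
        "seed": spec.seed,
        "threshold": threshold,
        "n_folds": len(per_fold),
        "roc_average": average,
    }
    return pooled
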