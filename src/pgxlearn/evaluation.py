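"""Prediction-quality metrics and the repeated k-fold cross-validation engine.

Regression quality is RMSE; classification quality is accuracy / precision /
recall / F-score from confusion counts, AUC from class-2 probabilities, and
the Hand–Till M statistic (``multiclass_auc``) for three classes — the average
over unordered class pairs (i, j) of ½[A(i|j) + A(j|i)], each term an AUC
computed on the samples of the two classes using the relevant probability
column.

Generalization error is estimated by 10×10-fold cross-validation: a 10-fold
CV repeated ten times with fresh partitions. Within one repetition every
sample is predicted exactly once; the out-of-fold predictions are pooled and
the metric computed once per repetition (so rank metrics remain well defined
on small folds). The summary statistic of record is the median over
repetitions; the mean is also reported. All tuning, PCA projection and
feature selection happen inside the training part of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from ._util import derive_seed

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "UndefinedMetricError",
    "rmse",
    "accuracy",
    "precision",
    "recall",
    "f_score",
    "roc_auc",
    "multiclass_auc",
    "compute_metric",
    "metric_direction",
    "kfold_partitions",
    "cross_validate",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator vanished or a required class is absent."""


def rmse(predicted, actual) -> float:
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def accuracy(cc: ConfusionCounts) -> float:
    if cc.total == 0:
        raise UndefinedMetricError("no evaluated samples")
    return (cc.tp + cc.tn) / cc.total


def precision(cc: ConfusionCounts) -> float:
    if cc.tp + cc.fp == 0:
        raise UndefinedMetricError("no positive predictions")
    return cc.tp / (cc.tp + cc.fp)


def recall(cc: ConfusionCounts) -> float:
    if cc.tp + cc.fn == 0:
        raise UndefinedMetricError("no positive samples")
    return cc.tp / (cc.tp + cc.fn)


def f_score(cc: ConfusionCounts, beta: float = 1.0) -> float:
    p, r = precision(cc), recall(cc)
    if p + r == 0:
        raise UndefinedMetricError("precision + recall is zero")
    b2 = beta**2
    return (1 + b2) * p * r / (b2 * p + r)


def roc_auc(scores, labels) -> float:
    """AUC of class-2 probabilities: P(random positive outscores a random
    negative), ties counting one half (rank-statistic formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("both classes must be present")
    return float(roc_auc_score((labels == np.max(labels)).astype(int), scores))


def multiclass_auc(prob, labels) -> float:
    """Hand–Till M over the classes present in ``labels``.

    ``prob`` columns correspond to ``sorted(set(labels))``; rows must sum to 1.
    For two classes this reduces to ``roc_auc`` on the second column.
    """
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise UndefinedMetricError("need at least two classes")
    if prob.shape != (len(labels), len(classes)):
        raise ValueError("probability matrix shape must be n_samples × n_present_classes")
    if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if len(classes) == 2:
        return roc_auc(prob[:, 1], labels)
    return float(roc_auc_score(labels, prob, multi_class="ovo", average="macro", labels=classes))


_METRIC_DIRECTION = {
    "RMSE": "lower_better",
    "AUC": "higher_better",
    "mAUC": "higher_better",
    "Accuracy": "higher_better",
    "F1": "higher_better",
}


def metric_direction(metric_name: str) -> str:
    return _METRIC_DIRECTION[metric_name]


def compute_metric(metric_name, y_true, y_pred, proba=None, classes=None) -> float:
    """Evaluate one named metric on pooled out-of-fold predictions.

    ``proba`` (samples × classes, columns per ``classes``) is required for AUC
    and mAUC; F1 is macro-averaged over the present classes.
    """
    if metric_name == "RMSE":
        return rmse(y_pred, y_true)
    y_true = np.asarray(y_true)
    if metric_name == "Accuracy":
        return float(np.mean(np.asarray(y_pred) == y_true))
    if metric_name == "F1":
        return float(f1_score(y_true, y_pred, average="macro", zero_division=0.0))
    if proba is None or classes is None:
        raise ValueError(f"{metric_name} requires class probabilities")
    classes = np.asarray(classes)
    present = np.unique(y_true)
    keep = np.isin(classes, present)
    sub = np.asarray(proba, dtype=float)[:, keep]
    row_sums = sub.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise UndefinedMetricError("zero probability mass on present classes")
    sub = sub / row_sums
    if metric_name == "AUC":
        if len(present) != 2:
            raise UndefinedMetricError("AUC needs exactly two present classes")
        return roc_auc(sub[:, 1], y_true)
    if metric_name == "mAUC":
        return multiclass_auc(sub, y_true)
    raise ValueError(f"unknown metric {metric_name!r}")


def kfold_partitions(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint index folds covering 0..n−1, sizes differing by at most one."""
    if k > n:
        raise ValueError("k must not exceed n")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


@dataclass
class CVResult:
    """Per-repetition pooled metric values of a repeated k-fold CV."""

    metric_name: str
    per_repeat: np.ndarray  # NaN marks a repetition whose metric was undefined
    k: int
    repeats: int
    seed: int
    n: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def valid(self) -> np.ndarray:
        return self.per_repeat[np.isfinite(self.per_repeat)]

    @property
    def median(self) -> float:
        if len(self.valid) == 0:
            return float("nan")
        return float(np.median(self.valid))

    @property
    def mean(self) -> float:
        if len(self.valid) == 0:
            return float("nan")
        return float(np.mean(self.valid))


def single_cv_predictions(spec, X, y, folds, seed: int = 0):
    """One k-fold pass: pooled out-of-fold predictions plus per-fold models.

    Returns ``(y_pred, proba, models)`` where ``proba`` is None unless the
    spec's metric needs class probabilities; ``models[i]`` was fit with fold
    ``i`` held out. Exposed so callers can inspect what each fold's fit
    actually used (e.g. to verify that held-out rows never influence in-fold
    PCA or gene selection).
    """
    from . import models as models_mod
    from .labeling import LabelSet

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    metric_name = models_mod.metric_for(spec)
    classes = np.unique(y.values) if y.is_classification else None
    needs_proba = metric_name in ("AUC", "mAUC")
    y_pred = np.empty(n, dtype=float)
    proba = np.zeros((n, len(classes))) if needs_proba else None
    fitted = []
    for f_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_train = LabelSet(y.labeling_kind, y.values[train_idx], y.thresholds)
        model = models_mod.fit(spec, X[train_idx], y_train, seed=derive_seed(seed, 2001, f_idx))
        fitted.append(model)
        y_pred[test_idx] = model.predict(X[test_idx])
        if needs_proba:
            p = model.predict_proba(X[test_idx])
            for j, c in enumerate(model.classes_):
                proba[test_idx, np.searchsorted(classes, c)] = p[:, j]
    return y_pred, proba, fitted


def cross_validate(spec, X, y, k: int = 10, repeats: int = 10, seed: int = 0) -> CVResult:
    """Repeated k-fold CV of one model specification.

    ``y`` is a :class:`~pgxlearn.labeling.LabelSet`. Each repetition uses a
    fresh seeded partition; models are fit on the training part only (the fit
    routine performs any tuning, projection or gene selection internally) and
    the held-out predictions are pooled before the metric is evaluated.
    """
    from . import models  # deferred: models imports the metric suite above
    from .labeling import LabelSet

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError("fewer samples than folds")
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    metric_name = models.metric_for(spec)
    classes = np.unique(y.values) if y.is_classification else None

    per_repeat = np.full(repeats, np.nan)
    messages: list[str] = []
    for r in range(repeats):
        folds = kfold_partitions(n, k, derive_seed(seed, 1001, r))
        try:
            y_pred, proba, _ = single_cv_predictions(spec, X, y, folds, seed=derive_seed(seed, 1002, r))
            per_repeat[r] = compute_metric(metric_name, y.values, y_pred, proba, classes)
        except (UndefinedMetricError, models.DegenerateFoldError) as exc:
            messages.append(f"repetition {r} invalid: {exc}")
    return CVResult(metric_name, per_repeat, k, repeats, seed, n=n, messages=messages)
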