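"""Confusion metrics, ROC/AUC, stratified k-fold CV and the jackknife.

Metrics follow the standard binary conventions, reported as percentages:

    Sn  = TP / (TP + FN) * 100            (sensitivity, virion recall)
    Sp  = TN / (TN + FP) * 100            (specificity)
    Acc = (TP + TN) / N * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) * 100

MCC with any zero marginal is defined as 0.  Cross-validation pools the
confusion counts across folds before computing the headline metrics (rather
than averaging per-fold percentages), and the AUC is computed from the
pooled out-of-fold positive-class posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .discretization import discretize, fit_discretizer
from .errors import InvalidArgumentError
from .mnb import fit_mnb, predict
from .selection import anova_f, rank_features


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix cells."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidArgumentError("confusion counts must be >= 0")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise InvalidArgumentError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass
class EvalResult:
    """Headline percentages plus optional AUC and per-fold breakdown."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    fold_counts: list[ConfusionCounts] = field(default_factory=list)


def metrics(c: ConfusionCounts) -> EvalResult:
    """Sensitivity, specificity, accuracy and MCC as percentages."""
    sn = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    sp = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = 100.0 * (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return EvalResult(c, sn, sp, acc, mcc)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep over distinct score thresholds and the trapezoidal AUC.

    Returns (fpr, tpr, thresholds, auc).  The trapezoidal area equals the
    Mann-Whitney concordance probability, with tied scores contributing 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise InvalidArgumentError("ROC needs both classes present")
    fpr, tpr, thresholds = _roc_curve(labels, scores)
    return fpr, tpr, thresholds, float(_trapezoid_auc(fpr, tpr))


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == positive) & (y_pred == positive))),
        tn=int(np.sum((y_true != positive) & (y_pred != positive))),
        fp=int(np.sum((y_true != positive) & (y_pred == positive))),
        fn=int(np.sum((y_true == positive) & (y_pred != positive))),
    )


def _fit_score_split(values, labels, train_idx, test_idx, config):
    """Rank -> discretize -> MNB on one train/test split.

    Returns (predicted labels, positive posteriors) for the test rows.
    """
    k = config.n_features or values.shape[1]
    k = min(k, values.shape[1])
    if config.leakage == "fold":
        rank = rank_features(anova_f(values[train_idx], labels[train_idx]))
        cols = rank[:k]
        disc = fit_discretizer(values[np.ix_(train_idx, cols)])
    else:
        rank = rank_features(anova_f(values, labels))
        cols = rank[:k]
        disc = fit_discretizer(values[:, cols])
    x_train = discretize(values[np.ix_(train_idx, cols)], disc)
    x_test = discretize(values[np.ix_(test_idx, cols)], disc)
    model = fit_mnb(x_train, labels[train_idx], alpha=config.alpha)
    preds = predict(model, x_test)
    return (
        np.array([p.predicted_class for p in preds]),
        np.array([p.positive_score for p in preds]),
    )


def kfold_cv(matrix, labels, config, k: int = 10, seed: int = 0) -> EvalResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold, feature ranking, discretization and the classifier are fitted
    per the configured leakage policy and scored on the held-out rows; the
    headline metrics come from the pooled confusion counts, the AUC from the
    pooled out-of-fold posteriors.  ``k == N`` degenerates to the jackknife
    (stratification is impossible, so plain leave-one-out splits are used).
    """
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if k == n:
        splits = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    else:
        counts = np.bincount(labels)
        if counts[counts > 0].min() < k:
            raise InvalidArgumentError(
                f"every class needs >= {k} samples for {k}-fold stratification"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(values, labels))

    fold_counts: list[ConfusionCounts] = []
    pooled_scores = np.empty(n)
    pooled_preds = np.empty(n, dtype=np.int64)
    for train_idx, test_idx in splits:
        y_pred, y_score = _fit_score_split(
            values, labels, train_idx, test_idx, config
        )
        pooled_preds[test_idx] = y_pred
        pooled_scores[test_idx] = y_score
        fold_counts.append(
            confusion_from_predictions(labels[test_idx], y_pred)
        )

    pooled = confusion_from_predictions(labels, pooled_preds)
    result = metrics(pooled)
    result.auc = roc_auc(pooled_scores, labels)[3]
    result.fold_counts = fold_counts
    return result


def jackknife(matrix, labels, config) -> EvalResult:
    """Leave-one-out cross-validation (deterministic, no shuffling)."""
    labels = np.asarray(labels)
    if len(labels) < 3:
        raise InvalidArgumentError("jackknife needs at least 3 samples")
    return kfold_cv(matrix, labels, config, k=len(labels))
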