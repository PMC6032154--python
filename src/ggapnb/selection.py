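"""ANOVA F-ratio feature ranking and incremental feature selection.

The discriminative power of each density feature is scored by the one-way
ANOVA F ratio

    F_j = [SS_between / (M - 1)] / [SS_within / (N - M)]

with M classes and N samples.  Features are ranked by F descending (ties
broken by column index) and the optimal prefix length K is chosen by
incremental feature selection: for each candidate K the full downstream
pipeline (discretize -> multinomial naive Bayes) is cross-validated on the
top-K columns and the K with the highest mean accuracy wins (smallest K on
ties).

Degenerate columns: zero variance everywhere gives F = 0 by convention;
zero within-class variance with distinct class means gives F = +inf, which
ranks above every finite score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .discretization import discretize, fit_discretizer
from .errors import InvalidArgumentError
from .mnb import fit_mnb, predict


@dataclass
class FScoreTable:
    """Per-column F ratios with their sum-of-squares components."""

    f_values: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    df_between: int
    df_within: int


@dataclass
class SelectionResult:
    """Ranked columns plus the accuracy-vs-K curve from incremental search."""

    ranked_columns: np.ndarray
    accuracy_curve: list[tuple[int, float]]
    best_k: int
    fold_accuracies: dict[int, list[float]] = field(default_factory=dict)


def anova_f(values: np.ndarray, labels: np.ndarray) -> FScoreTable:
    """One-way ANOVA F ratio for every column of a samples x features matrix.

    ``labels`` assigns each row to a class; at least two classes are
    required and N > M so the within-class degrees of freedom are positive.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.ndim != 2 or values.shape[0] != labels.shape[0]:
        raise InvalidArgumentError("values rows must align with labels")
    classes, inverse = np.unique(labels, return_inverse=True)
    M, N = len(classes), len(labels)
    if M < 2:
        raise InvalidArgumentError("ANOVA needs at least two classes")
    if N - M < 1:
        raise InvalidArgumentError("ANOVA needs N >= M + 1 samples")

    grand_mean = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for mu in range(M):
        group = values[inverse == mu]
        gmean = group.mean(axis=0)
        ss_between += len(group) * (gmean - grand_mean) ** 2
        ss_within += ((group - gmean) ** 2).sum(axis=0)

    ms_between = ss_between / (M - 1)
    ms_within = ss_within / (N - M)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    # 0/0 (constant column) -> 0; x/0 with x>0 stays +inf (perfect separator)
    f[np.isnan(f)] = 0.0
    return FScoreTable(f, ss_between, ss_within, M - 1, N - M)


def rank_features(table: FScoreTable) -> np.ndarray:
    """Column indices sorted by F descending, ties by ascending index."""
    return np.argsort(-table.f_values, kind="stable")


def _clean_ks(ks, n_features: int) -> list[int]:
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise InvalidArgumentError("ks must be non-empty")
    if ks[0] < 1 or ks[-1] > n_features:
        raise InvalidArgumentError(
            f"every K must lie in [1, {n_features}], got {ks[0]}..{ks[-1]}"
        )
    return ks


def incremental_selection(
    matrix,
    labels: np.ndarray,
    ks,
    n_folds: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
    leakage: str = "fold",
) -> SelectionResult:
    """Accuracy-vs-K curve under stratified cross-validation.

    For each fold, features are ranked and the discretizer fitted on the
    training rows only (``leakage='fold'``, the default) or once on the full
    dataset (``leakage='global'``, reproducing the simpler protocol some
    published pipelines use).  Because top-K prefixes are nested, each fold
    ranks once and reuses the ranking for every K.
    """
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    labels = np.asarray(labels)
    ks = _clean_ks(ks, values.shape[1])
    if leakage not in ("fold", "global"):
        raise InvalidArgumentError(f"unknown leakage policy {leakage!r}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_k_hits: dict[int, list[float]] = {k: [] for k in ks}

    if leakage == "global":
        global_rank = rank_features(anova_f(values, labels))
        global_disc = fit_discretizer(values)

    for train_idx, test_idx in skf.split(values, labels):
        if leakage == "fold":
            rank = rank_features(anova_f(values[train_idx], labels[train_idx]))
            disc_source = values[train_idx]
        else:
            rank = global_rank
        for k in ks:
            cols = rank[:k]
            if leakage == "fold":
                disc = fit_discretizer(disc_source[:, cols])
            else:
                disc = global_disc.subset(cols)
            x_train = discretize(values[np.ix_(train_idx, cols)], disc)
            x_test = discretize(values[np.ix_(test_idx, cols)], disc)
            model = fit_mnb(x_train, labels[train_idx], alpha=alpha)
            preds = predict(model, x_test)
            acc = np.mean(
                [p.predicted_class == y for p, y in zip(preds, labels[test_idx])]
            )
            per_k_hits[k].append(float(acc))

    curve = [(k, float(np.mean(per_k_hits[k]))) for k in ks]
    best_k = max(curve, key=lambda ka: (ka[1], -ka[0]))[0]
    full_rank = rank_features(anova_f(values, labels))
    return SelectionResult(full_rank, curve, best_k, per_k_hits)
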