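"""Multinomial naive Bayes on discrete {0, 1, 2} feature vectors.

The class-conditional likelihood of a feature vector x is modelled as a
multinomial over the n feature columns, treating each discrete level as a
count.  With per-class column totals n_j^(mu) and pseudo-count alpha, the
smoothed event probabilities are

    theta_{mu,j} = (n_j^(mu) + alpha) / (sum_j n_j^(mu) + n * alpha)

and a row is scored by log P(y=mu) + sum_j x_j * log theta_{mu,j}.  All
computation is in the log domain, so scores stay finite for vocabularies of
tens of thousands of columns.  Ties in the posterior are broken toward the
smaller class label (the negative, non-virion class in the binary setting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidArgumentError


@dataclass
class MNBModel:
    """Fitted priors and per-class log event probabilities."""

    classes: np.ndarray
    class_log_priors: np.ndarray
    feature_log_probs: np.ndarray  # shape (n_classes, n_features)
    alpha: float

    @property
    def n_features(self) -> int:
        return self.feature_log_probs.shape[1]

    def to_json(self, path: str | Path, vocabulary_checksum: str = "") -> None:
        payload = {
            "vocabulary_checksum": vocabulary_checksum,
            "alpha": self.alpha,
            "classes": self.classes.tolist(),
            "class_log_priors": self.class_log_priors.tolist(),
            "feature_log_probs": self.feature_log_probs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MNBModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            classes=np.asarray(payload["classes"]),
            class_log_priors=np.asarray(payload["class_log_priors"]),
            feature_log_probs=np.asarray(payload["feature_log_probs"]),
            alpha=float(payload["alpha"]),
        )


@dataclass
class Prediction:
    """Predicted class with its normalized posterior distribution."""

    predicted_class: int
    posterior: np.ndarray
    positive_score: float  # posterior mass on the largest class label


def fit_mnb(
    matrix: np.ndarray, labels: np.ndarray, alpha: float = 1.0
) -> MNBModel:
    """Fit the smoothed multinomial model from discrete training rows."""
    if alpha <= 0:
        raise InvalidArgumentError("alpha must be > 0")
    X = np.asarray(matrix)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise InvalidArgumentError("matrix rows must align with labels")
    if np.any(X < 0) or not np.issubdtype(X.dtype, np.integer):
        raise InvalidArgumentError("entries must be non-negative integers")
    classes, inverse = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise InvalidArgumentError("need at least two classes")

    n = X.shape[1]
    log_priors = np.empty(len(classes))
    log_probs = np.empty((len(classes), n))
    for mu in range(len(classes)):
        rows = X[inverse == mu]
        log_priors[mu] = np.log(rows.shape[0] / X.shape[0])
        counts = rows.sum(axis=0).astype(np.float64)
        log_probs[mu] = np.log(counts + alpha) - np.log(
            counts.sum() + n * alpha
        )
    return MNBModel(classes, log_priors, log_probs, float(alpha))


def predict_log_posterior(
    model: MNBModel, row: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized per-class log scores and the normalized posterior."""
    row = np.asarray(row)
    if row.shape != (model.n_features,):
        raise InvalidArgumentError(
            f"row length {row.shape} != model features {model.n_features}"
        )
    scores = model.class_log_priors + model.feature_log_probs @ row
    posterior = np.exp(scores - logsumexp(scores))
    return scores, posterior


def predict(model: MNBModel, matrix: np.ndarray) -> list[Prediction]:
    """Row-wise prediction; ties go to the smaller class label."""
    X = np.asarray(matrix)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise InvalidArgumentError(
            f"matrix columns do not match model ({model.n_features})"
        )
    scores = model.class_log_priors + X @ model.feature_log_probs.T
    posteriors = np.exp(scores - logsumexp(scores, axis=1, keepdims=True))
    # argmax returns the first (smallest-label) index on exact ties
    winners = np.argmax(scores, axis=1)
    positive_col = int(np.argmax(model.classes))
    return [
        Prediction(
            predicted_class=model.classes[w],
            posterior=posteriors[i],
            positive_score=float(posteriors[i, positive_col]),
        )
        for i, w in enumerate(winners)
    ]
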