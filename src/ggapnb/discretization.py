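"""Median-cut discretization of density features into three levels.

Each continuous column is mapped to {0, 1, 2}: zeros stay 0 ("absent"); the
cutoff m is the median of the column's strictly positive training values;
values in (0, m] become 1 ("mid") and values in (m, inf) become 2 ("high").
A column with no positive training values is flagged ``all_zero``; at
transform time any positive value seen in such a column maps to 2, keeping
the labelling monotone in the raw value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class DiscretizationModel:
    """Per-column positive-median cutoffs, in the fitted column order."""

    cutoffs: np.ndarray
    all_zero: np.ndarray
    columns: np.ndarray | None = None  # source column indices, if subset

    @property
    def n_columns(self) -> int:
        return len(self.cutoffs)

    def subset(self, cols: np.ndarray) -> "DiscretizationModel":
        """Restriction of a full-matrix model to the given source columns."""
        cols = np.asarray(cols)
        return DiscretizationModel(
            cutoffs=self.cutoffs[cols],
            all_zero=self.all_zero[cols],
            columns=cols,
        )

    def to_json(self, path: str | Path, vocabulary_checksum: str = "") -> None:
        payload = {
            "vocabulary_checksum": vocabulary_checksum,
            "columns": (
                self.columns.tolist() if self.columns is not None else None
            ),
            "cutoffs": self.cutoffs.tolist(),
            "all_zero": self.all_zero.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationModel":
        payload = json.loads(Path(path).read_text())
        cols = payload["columns"]
        return cls(
            cutoffs=np.asarray(payload["cutoffs"], dtype=np.float64),
            all_zero=np.asarray(payload["all_zero"], dtype=bool),
            columns=None if cols is None else np.asarray(cols, dtype=np.int64),
        )


def fit_discretizer(values: np.ndarray, columns=None) -> DiscretizationModel:
    """Learn per-column cutoffs from training densities.

    The cutoff is the median of the strictly positive entries (an even count
    takes the mean of the two middle values); zeros are excluded, matching
    the convention that 0 is its own "absent" level.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 1:
        raise InvalidArgumentError("need a non-empty samples x features matrix")
    n_cols = values.shape[1]
    cutoffs = np.zeros(n_cols)
    all_zero = np.zeros(n_cols, dtype=bool)
    for j in range(n_cols):
        positive = values[values[:, j] > 0, j]
        if positive.size == 0:
            all_zero[j] = True
        else:
            cutoffs[j] = np.median(positive)
    return DiscretizationModel(
        cutoffs,
        all_zero,
        None if columns is None else np.asarray(columns, dtype=np.int64),
    )


def discretize(values: np.ndarray, model: DiscretizationModel) -> np.ndarray:
    """Map densities onto {0, 1, 2} using a fitted model.

    Columns must align with the model's fitted columns (same order, same
    count).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != model.n_columns:
        raise InvalidArgumentError(
            f"matrix has {values.shape[1] if values.ndim == 2 else '?'} "
            f"columns, model expects {model.n_columns}"
        )
    out = np.zeros(values.shape, dtype=np.int64)
    positive = values > 0
    out[positive] = 1
    out[positive & (values > model.cutoffs)] = 2
    # all-zero training columns: any positive mass counts as "high"
    if model.all_zero.any():
        az = np.broadcast_to(model.all_zero, values.shape)
        out[positive & az] = 2
    return out
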