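"""Density encoding of protein sequences over a gapped-pattern vocabulary.

For a sequence of length ``L`` and a pattern of width ``w``, every contiguous
window of width ``w`` (there are ``L' = L - w + 1`` of them) is compared to
the pattern: the window matches a feature when the characters at the
pattern's residue positions equal the feature's residue tuple; gap positions
match anything.  The density of a feature is the matching-window count
divided by ``L'``.  Densities therefore lie in [0, 1] and, for each pattern,
sum to exactly 1 across its instantiations whenever ``L >= w`` (each window
matches exactly one residue tuple).  Sequences shorter than the pattern
width receive density 0 for every instantiation of that pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .patterns import AMINO_ACIDS, Feature, FeatureVocabulary

_AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SequenceRecord:
    """A named protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    sequence: str

    def validate(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidArgumentError(f"record {self.id!r}: empty sequence")
        for ch in self.sequence:
            if ch not in _AA_CODE:
                raise InvalidArgumentError(
                    f"record {self.id!r}: invalid residue {ch!r}"
                )

    def codes(self) -> np.ndarray:
        """Sequence as integer codes 0..19 (alphabetical order)."""
        try:
            return np.fromiter(
                (_AA_CODE[ch] for ch in self.sequence),
                dtype=np.int64,
                count=len(self.sequence),
            )
        except KeyError as exc:
            raise InvalidArgumentError(
                f"record {self.id!r}: invalid residue {exc.args[0]!r}"
            ) from None


@dataclass
class DenseFeatureMatrix:
    """Samples x features density matrix tied to a vocabulary."""

    values: np.ndarray
    sample_ids: list[str]
    vocabulary: FeatureVocabulary

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.vocabulary)):
            raise InvalidArgumentError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x "
                f"{len(self.vocabulary)} features"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save_triplets(self, path) -> None:
        """Sparse text export: one `sample_id TAB column TAB value` per
        non-zero entry."""
        rows, cols = np.nonzero(self.values)
        with open(path, "w") as fh:
            for r, c in zip(rows, cols):
                fh.write(
                    f"{self.sample_ids[r]}\t{c}\t{float(self.values[r, c])!r}\n"
                )


def window_matches(window: str, feature: Feature) -> bool:
    """True iff the window realizes the feature (gaps are wildcards)."""
    pattern = feature.pattern
    if len(window) != pattern.width:
        raise InvalidArgumentError(
            f"window length {len(window)} != pattern width {pattern.width}"
        )
    return all(
        window[pos] == aa
        for pos, aa in zip(pattern.residue_positions, feature.residues)
    )


def density(record: SequenceRecord, feature: Feature) -> float:
    """Fraction of the record's sliding windows matching the feature.

    Returns 0.0 when the sequence is shorter than the pattern width.
    """
    record.validate()
    width = feature.pattern.width
    seq = record.sequence
    n_windows = len(seq) - width + 1
    if n_windows <= 0:
        return 0.0
    hits = sum(
        window_matches(seq[k : k + width], feature) for k in range(n_windows)
    )
    return hits / n_windows


def encode(
    records: list[SequenceRecord], vocab: FeatureVocabulary
) -> DenseFeatureMatrix:
    """Density matrix for all records over all vocabulary features.

    Rows follow input order; columns follow vocabulary order.  Each pattern's
    windows are scanned independently, so patterns of different widths have
    different window counts.
    """
    if not records:
        raise InvalidArgumentError("records must be non-empty")
    values = np.zeros((len(records), len(vocab)), dtype=np.float64)
    for i, rec in enumerate(records):
        rec.validate()
        codes = rec.codes()
        L = len(codes)
        for pattern in vocab.patterns:
            w = pattern.width
            n_windows = L - w + 1
            if n_windows <= 0:
                continue
            # base-20 column offset of each window's residue tuple
            col = np.zeros(n_windows, dtype=np.int64)
            for pos in pattern.residue_positions:
                col = col * 20 + codes[pos : pos + n_windows]
            counts = np.bincount(col, minlength=20**pattern.n_residues)
            sl = vocab.pattern_slice(pattern)
            values[i, sl] = counts / n_windows
    return DenseFeatureMatrix(values, [r.id for r in records], vocab)
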