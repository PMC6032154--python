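"""Gapped sequence patterns and the feature vocabulary they induce.

A pattern is a template over two symbols: ``x`` (any one of the 20 canonical
amino acids) and ``-`` (a gap position that matches any residue).  Templates
are generated by growing a binary tree from the root ``x``: a left child
appends ``x``, a right child appends ``-``, and a branch stops once appending
would exceed the residue or gap budget.  Templates that begin or end with a
gap are discarded; with the default budgets (three residues, two gaps) exactly
ten templates survive::

    x  xx  xxx  x-x  x-xx  xx-x  x--x  x--xx  xx--x  x-x-x

Instantiating every template with all concrete residue tuples yields the
feature vocabulary: 20 + 3*400 + 6*8000 = 49,220 features at the defaults.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import InvalidArgumentError

#: The 20 canonical amino acids, alphabetically ordered.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

RESIDUE = "x"
GAP = "-"

#: Default tree budgets reproducing the ten-template pattern set.
DEFAULT_MAX_RESIDUES = 3
DEFAULT_MAX_GAPS = 2


@dataclass(frozen=True, order=True)
class GGapPattern:
    """A gapped template such as ``x-x`` (two residues separated by a gap)."""

    template: str

    def __post_init__(self) -> None:
        t = self.template
        if not t or set(t) - {RESIDUE, GAP}:
            raise InvalidArgumentError(
                f"template must be a non-empty string over {{'x', '-'}}: {t!r}"
            )
        if t[0] != RESIDUE or t[-1] != RESIDUE:
            raise InvalidArgumentError(
                f"template must begin and end with a residue symbol: {t!r}"
            )

    @property
    def n_residues(self) -> int:
        return self.template.count(RESIDUE)

    @property
    def n_gaps(self) -> int:
        return self.template.count(GAP)

    @property
    def width(self) -> int:
        return len(self.template)

    @property
    def residue_positions(self) -> tuple[int, ...]:
        """Offsets within a window that must match concrete residues."""
        return tuple(i for i, s in enumerate(self.template) if s == RESIDUE)

    def __str__(self) -> str:
        return self.template


@dataclass(frozen=True)
class Feature:
    """A concrete instantiation of a pattern, e.g. ``(x-x, (A, C))``."""

    pattern: GGapPattern
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != self.pattern.n_residues:
            raise InvalidArgumentError(
                f"pattern {self.pattern} needs {self.pattern.n_residues} "
                f"residues, got {self.residues!r}"
            )
        for aa in self.residues:
            if aa not in AMINO_ACIDS:
                raise InvalidArgumentError(f"non-canonical residue {aa!r}")

    def __str__(self) -> str:
        return f"{self.pattern.template}:{''.join(self.residues)}"


def expand_feature_tree(
    max_residues: int = DEFAULT_MAX_RESIDUES, max_gaps: int = DEFAULT_MAX_GAPS
) -> list[str]:
    """Enumerate every template generated by the binary feature tree.

    The root template is ``x``; expanding a node appends ``x`` (left child)
    or ``-`` (right child), and a child is only created while it respects the
    residue and gap budgets.  All generated templates are returned in
    depth-first pre-order, left child first, with no admissibility filtering.
    """
    if max_residues < 1:
        raise InvalidArgumentError("max_residues must be >= 1")
    if max_gaps < 0:
        raise InvalidArgumentError("max_gaps must be >= 0")

    out: list[str] = []

    def visit(template: str, n_res: int, n_gap: int) -> None:
        out.append(template)
        if n_res + 1 <= max_residues:
            visit(template + RESIDUE, n_res + 1, n_gap)
        if n_gap + 1 <= max_gaps:
            visit(template + GAP, n_res, n_gap + 1)

    visit(RESIDUE, 1, 0)
    return out


def _canonical_key(template: str) -> tuple[int, int, int, str]:
    # fewest gaps, then fewest residues, then contiguous gap blocks before
    # split ones, then lexicographic ('-' sorts before 'x')
    n_gap_runs = len([r for r in template.split(RESIDUE) if r])
    return (
        template.count(GAP),
        template.count(RESIDUE),
        n_gap_runs,
        template,
    )


def admissible_patterns(
    max_residues: int = DEFAULT_MAX_RESIDUES, max_gaps: int = DEFAULT_MAX_GAPS
) -> list[GGapPattern]:
    """The tree's templates that neither begin nor end with a gap.

    Returned in the canonical order (fewest gaps first, then fewest residues,
    then lexicographic); the defaults yield the ten standard templates.
    """
    templates = expand_feature_tree(max_residues, max_gaps)
    keep = [t for t in templates if t[0] == RESIDUE and t[-1] == RESIDUE]
    return [GGapPattern(t) for t in sorted(keep, key=_canonical_key)]


@dataclass
class FeatureVocabulary:
    """Ordered list of features with a stable feature -> column bijection.

    Features are grouped by pattern, patterns in the order supplied to
    :func:`build_vocabulary`, and within a pattern the residue tuples run in
    lexicographic order — so the column index of an instantiation is its
    pattern's base offset plus the base-20 value of its residue tuple.
    """

    patterns: list[GGapPattern]
    _offsets: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._offsets = []
        total = 0
        for p in self.patterns:
            self._offsets.append(total)
            total += 20**p.n_residues
        self._size = total

    def __len__(self) -> int:
        return self._size

    def __iter__(self) -> Iterator[Feature]:
        for p in self.patterns:
            for combo in itertools.product(AMINO_ACIDS, repeat=p.n_residues):
                yield Feature(p, combo)

    def __getitem__(self, index: int) -> Feature:
        if not 0 <= index < self._size:
            raise IndexError(index)
        for p, base in zip(reversed(self.patterns), reversed(self._offsets)):
            if index >= base:
                combo = []
                rem = index - base
                for _ in range(p.n_residues):
                    rem, digit = divmod(rem, 20)
                    combo.append(AMINO_ACIDS[digit])
                return Feature(p, tuple(reversed(combo)))
        raise IndexError(index)  # pragma: no cover

    def index_of(self, feature: Feature) -> int:
        """Column index of a feature (pattern base offset + base-20 encoding
        of its residue tuple)."""
        try:
            base = self._offsets[self.patterns.index(feature.pattern)]
        except ValueError:
            raise InvalidArgumentError(
                f"pattern {feature.pattern} not in vocabulary"
            ) from None
        idx = 0
        for aa in feature.residues:
            idx = idx * 20 + AMINO_ACIDS.index(aa)
        return base + idx

    def pattern_slice(self, pattern: GGapPattern) -> slice:
        """Column range holding all instantiations of one pattern."""
        i = self.patterns.index(pattern)
        return slice(self._offsets[i], self._offsets[i] + 20**pattern.n_residues)

    @property
    def checksum(self) -> str:
        """SHA-256 over the pattern templates in order (identifies columns)."""
        joined = "\n".join(p.template for p in self.patterns)
        return hashlib.sha256(joined.encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        """Write one feature per line: template TAB residues TAB column."""
        with open(path, "w") as fh:
            for i, feat in enumerate(self):
                fh.write(
                    f"{feat.pattern.template}\t{''.join(feat.residues)}\t{i}\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureVocabulary":
        patterns: list[GGapPattern] = []
        expected = 0
        with open(path) as fh:
            for line in fh:
                template, residues, col = line.rstrip("\n").split("\t")
                if not patterns or patterns[-1].template != template:
                    patterns.append(GGapPattern(template))
                if int(col) != expected:
                    raise InvalidArgumentError(
                        f"non-contiguous column index {col} in {path}"
                    )
                expected += 1
        vocab = cls(patterns)
        if len(vocab) != expected:
            raise InvalidArgumentError(
                f"vocabulary file {path} is truncated "
                f"({expected} rows, expected {len(vocab)})"
            )
        return vocab


def build_vocabulary(
    patterns: Iterable[GGapPattern] | None = None,
) -> FeatureVocabulary:
    """Instantiate patterns into the ordered feature vocabulary.

    With no argument, uses the ten default admissible patterns (49,220
    features).
    """
    pats = list(patterns) if patterns is not None else admissible_patterns()
    if not pats:
        raise InvalidArgumentError("patterns must be non-empty")
    if len(set(pats)) != len(pats):
        raise InvalidArgumentError("duplicate patterns")
    return FeatureVocabulary(pats)
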