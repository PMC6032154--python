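"""FASTA and label-file ingestion with an explicit ambiguous-residue policy.

Benchmark construction in this problem domain drops sequences containing
ambiguous residues (X, B, Z and other non-canonical letters); the reader
reproduces that as ``policy='reject'`` (drop with a logged warning) or
``policy='error'`` (abort on the first offending record).
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO

from .encoding import SequenceRecord
from .errors import DataError, FastaFormatError, InvalidArgumentError
from .patterns import AMINO_ACIDS

logger = logging.getLogger("ggapnb")

_CANONICAL = set(AMINO_ACIDS)


def read_fasta(path: str | Path, policy: str = "reject") -> list[SequenceRecord]:
    """Read records in file order; ids are the first header token.

    Sequences are upper-cased.  Records with non-canonical residues are
    dropped (policy='reject', with a warning) or abort the read
    (policy='error').
    """
    if policy not in ("reject", "error"):
        raise InvalidArgumentError(f"unknown residue policy {policy!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty file")
    first = next(
        (ln for ln in text.splitlines() if ln.strip()), ""
    )
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: sequence data before first header")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - _CANONICAL)
        if bad:
            if policy == "error":
                raise DataError(
                    f"record {rec.id!r} contains non-canonical "
                    f"residue(s) {''.join(bad)}"
                )
            logger.warning(
                "dropping record %r: non-canonical residue(s) %s",
                rec.id,
                "".join(bad),
            )
            continue
        if not seq:
            logger.warning("dropping record %r: empty sequence", rec.id)
            continue
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Two-column TSV: record id TAB label (0/1)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FastaFormatError(
                f"{path}:{lineno}: expected 'id<TAB>label'"
            )
        rid, lab = parts
        if lab not in ("0", "1"):
            raise DataError(f"{path}:{lineno}: label must be 0 or 1")
        labels[rid] = int(lab)
    if not labels:
        raise DataError(f"{path}: no labels found")
    return labels


def write_labels(records, labels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec, lab in zip(records, labels):
            fh.write(f"{rec.id}\t{int(lab)}\n")
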