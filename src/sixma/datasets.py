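"""Labeled fixed-length DNA window datasets.

A dataset is an ordered collection of equal-length windows over {A,C,G,T},
each labeled 1 (modified central adenine, 6mA-positive) or 0 (negative).
Windows are read from a pair of FASTA files (one per class) or from a
2-column TSV (sequence, label); both formats round-trip exactly.

Ambiguous bases (N, IUPAC codes, gaps) are rejected rather than coerced:
every downstream encoding is a per-position statistic and silently mapping
N to some base would corrupt the position counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, EmptyClassError, LengthMismatchError

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window with a binary 6mA label."""

    id: str
    seq: str
    label: int

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid character(s) {sorted(bad)}; "
                "only A, C, G, T are accepted (ambiguous bases are rejected, "
                "not coerced)"
            )
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


class LabeledDataset:
    """Ordered, validated collection of equal-length labeled windows.

    Parameters
    ----------
    records
        SequenceRecord instances. All must share one length; an empty
        collection is allowed (the length is then undefined).
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            ref = len(self.records[0].seq)
            offender = next(r for r in self.records if len(r.seq) != ref)
            raise LengthMismatchError(
                f"record {offender.id!r} has length {len(offender.seq)}, "
                f"expected {ref} (all windows in a dataset must share one length)"
            )
        self.length: int | None = lengths.pop() if lengths else None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabeledDataset) and self.records == other.records

    def __repr__(self) -> str:
        return (
            f"LabeledDataset(n={len(self)}, n_pos={self.n_pos}, "
            f"n_neg={self.n_neg}, L={self.length})"
        )

    # -- views ---------------------------------------------------------------
    @property
    def n_pos(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_neg(self) -> int:
        return sum(r.label == 0 for r in self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(self.records[i] for i in indices)

    def fingerprint(self) -> str:
        """Stable hash of (seq, label) content, used to record exactly which
        records a label-dependent statistic was fitted on."""
        import hashlib

        h = hashlib.sha256()
        for r in self.records:
            h.update(r.seq.encode())
            h.update(b"\x00" if r.label == 0 else b"\x01")
        return h.hexdigest()[:16]

    def require_both_classes(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise EmptyClassError(
                f"operation requires at least one record of each class "
                f"(got n_pos={self.n_pos}, n_neg={self.n_neg})"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _read_fasta_class(path, label: int) -> list[SequenceRecord]:
    recs = [
        SequenceRecord(id=rec.id, seq=str(rec.seq), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not recs:
        cls = "positive" if label == 1 else "negative"
        raise EmptyClassError(f"{cls} FASTA file {path!s} contains no records")
    return recs


def read_labeled_fasta(pos_path, neg_path) -> LabeledDataset:
    """Read one FASTA of positive windows and one of negatives.

    Positives keep their file order and come first; negatives follow.
    Lowercase letters are normalized to uppercase; any non-ACGT character
    raises :class:`AlphabetError` naming the record.
    """
    return LabeledDataset(_read_fasta_class(pos_path, 1) + _read_fasta_class(neg_path, 0))


def write_labeled_fasta(ds: LabeledDataset, pos_path, neg_path) -> None:
    """Write the two classes back to a pair of FASTA files."""
    pos = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in ds if r.label == 1]
    neg = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in ds if r.label == 0]
    SeqIO.write(pos, str(pos_path), "fasta")
    SeqIO.write(neg, str(neg_path), "fasta")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_dataset_tsv(ds: LabeledDataset, path) -> None:
    """Write a 2-column TSV (sequence, label) with a header row.

    Labels are written as literal 0/1 integers; an empty dataset produces a
    header-only file. Round-trips bit-exactly through
    :func:`read_dataset_tsv` up to record ids (ids become row numbers).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "label"])
        for r in ds:
            w.writerow([r.seq, int(r.label)])


def read_dataset_tsv(path) -> LabeledDataset:
    """Read a 2-column TSV (sequence, label); header row required."""
    records: list[SequenceRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["sequence", "label"]:
            raise ValueError(f"{path!s}: expected header 'sequence\\tlabel'")
        for i, row in enumerate(reader):
            if not row:
                continue
            seq, label = row[0], row[1]
            if label not in ("0", "1"):
                raise ValueError(f"{path!s} row {i + 1}: label must be 0 or 1, got {label!r}")
            records.append(SequenceRecord(id=f"row{i + 1}", seq=seq, label=int(label)))
    return LabeledDataset(records)
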