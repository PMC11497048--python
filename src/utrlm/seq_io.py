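"""Sequence and interval I/O plus windowing and redundancy filtering.

All sequences are normalized to the RNA alphabet {A, C, G, U, N} on read
(T -> U, lowercase uppercased). Coordinates are 0-based half-open
internally; 1-based coordinates appear only in human-readable messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

RNA_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence after normalization."""

    id: str
    sequence: str
    source_alphabet: str = "RNA"  # "DNA" if the raw input contained T

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = next(
            ((i, c) for i, c in enumerate(self.sequence) if c not in RNA_ALPHABET),
            None,
        )
        if bad is not None:
            i, c = bad
            raise ValueError(
                f"record {self.id!r}: illegal character {c!r} at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval {self.name!r} on {self.seq_id!r}: "
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def normalize_sequence(raw: str, record_id: str = "?") -> tuple[str, str]:
    """Uppercase, map T->U, and validate; returns (sequence, source_alphabet)."""
    up = raw.upper()
    alphabet = "DNA" if "T" in up else "RNA"
    seq = up.replace("T", "U")
    for i, c in enumerate(seq):
        if c not in RNA_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: illegal character {raw[i]!r} at position {i + 1}"
            )
    return seq, alphabet


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq, alphabet = normalize_sequence(str(rec.seq), rec.id)
        records.append(SequenceRecord(rec.id, seq, alphabet))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(Path(path)), "fasta")


def window_sequence(
    record: SequenceRecord, window: int = 510
) -> list[tuple[str, Interval]]:
    """Split a sequence into non-overlapping left-to-right windows.

    The final fragment is emitted unpadded (its interval records the true
    extent); padding to the model length happens at the token level with
    [PAD] ids in :func:`utrlm.tokenizer.encode`, so sequence files stay
    faithful to the input.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    L = len(record.sequence)
    out: list[tuple[str, Interval]] = []
    for start in range(0, L, window):
        end = min(start + window, L)
        out.append(
            (
                record.sequence[start:end],
                Interval(record.id, start, end, name=f"{record.id}:{start}-{end}"),
            )
        )
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped end-to-end identity over the shorter length."""
    L = min(len(a), len(b))
    if L == 0:
        raise ValueError("cannot compare empty sequences")
    return sum(x == y for x, y in zip(a[:L], b[:L])) / L


def redundancy_filter(
    records: Sequence[SequenceRecord], identity_cutoff: float
) -> list[SequenceRecord]:
    """Greedy keep-first redundancy filter.

    A record is dropped iff its ungapped identity to an already-kept record
    is >= the cutoff. Deterministic given input order; a lightweight internal
    stand-in for external clustering tools.
    """
    if not (0.0 < identity_cutoff <= 1.0):
        raise ValueError(f"identity cutoff must be in (0, 1], got {identity_cutoff}")
    kept: list[SequenceRecord] = []
    for rec in records:
        if all(
            pairwise_identity(rec.sequence, k.sequence) < identity_cutoff for k in kept
        ):
            kept.append(rec)
    return kept


# --- BED6 ---------------------------------------------------------------


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t+\n"
            )


def read_bed(path: str | Path) -> list[Interval]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            try:
                out.append(Interval(fields[0], start, end, score, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


# --- labeled TSV ---------------------------------------------------------


def write_labeled_tsv(
    rows: Iterable[tuple[str, str | Sequence[int]]], path: str | Path
) -> None:
    """Write (sequence, label) rows; multi-labels joined with commas."""
    with open(path, "w") as fh:
        for seq, label in rows:
            if not isinstance(label, str):
                label = ",".join(str(int(b)) for b in label)
            fh.write(f"{seq}\t{label}\n")


def read_labeled_tsv(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sequence<TAB>label'")
            out.append((parts[0], parts[1]))
    return out
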