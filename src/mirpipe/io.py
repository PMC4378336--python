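"""Sequence input/output and read collapsing.

Small-RNA libraries are handled as collections of :class:`SequenceRecord`
(raw reads) which are collapsed into unique :class:`SmallRNATag` objects
carrying a *redundant* read count — the unique/redundant distinction that
underlies every downstream expression figure.

Supported formats: FASTA, FASTQ (Sanger qualities) and "collapsed FASTA",
where the header itself carries the read count.  Two collapsed-header
dialects are auto-detected on read (``>id_xN`` and ``>id count=N``); the
writer always emits ``>tagK_xN``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "SmallRNATag",
    "ParseError",
    "read_sequence_file",
    "collapse_tags",
    "expand_tags",
    "write_collapsed_fasta",
    "write_fasta",
    "write_tabular",
    "read_tabular",
]

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")

_COUNT_SUFFIX_X = re.compile(r"^(?P<name>.+)_x(?P<count>\d+)$")
_COUNT_SUFFIX_EQ = re.compile(r"^(?P<name>\S+)\s+count=(?P<count>\d+)$")


class ParseError(ValueError):
    """A sequence file violated the named standard."""


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U (internal alphabet is RNA)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


_RC_RNA = str.maketrans("ACGUN", "UGCAN")
_RC_DNA = str.maketrans("ACGTN", "TGCAN")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RC_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_RC_DNA)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with optional per-base quality.

    Invariants: non-empty sequence; quality (when present) has the same
    length as the sequence. ``count`` carries a collapsed-header read count
    (1 for ordinary records).
    """

    id: str
    sequence: str
    quality: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def mean_quality(self) -> float | None:
        if self.quality is None:
            return None
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


@dataclass(frozen=True)
class SmallRNATag:
    """A unique small-RNA sequence with its redundant read count."""

    sequence: str
    count: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"tag {self.id!r}: count must be >= 1, got {self.count}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"tag {self.id!r}: non-RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_collapsed_header(header: str) -> tuple[str, int]:
    m = _COUNT_SUFFIX_X.match(header)
    if m:
        return m.group("name"), int(m.group("count"))
    m = _COUNT_SUFFIX_EQ.match(header)
    if m:
        return m.group("name"), int(m.group("count"))
    raise ParseError(
        f"collapsed-fasta header {header!r} carries no count suffix "
        "(expected '>id_xN' or '>id count=N')"
    )


def read_sequence_file(
    path: str | Path,
    format: str = "fasta",
    rna: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA / FASTQ / collapsed-FASTA file into records, in file order.

    With ``rna=True``, T is converted to U on read (the pipeline-internal
    alphabet is RNA).  Collapsed headers carry the redundant count.
    """
    path = Path(path)
    if format not in {"fasta", "fastq", "collapsed-fasta"}:
        raise ValueError(f"unknown format {format!r}")
    records: list[SequenceRecord] = []
    bioformat = "fastq" if format == "fastq" else "fasta"
    try:
        for rec in SeqIO.parse(str(path), bioformat):
            seq = str(rec.seq).upper()
            if rna:
                seq = to_rna(seq)
            quality = None
            if bioformat == "fastq":
                phred = rec.letter_annotations.get("phred_quality", [])
                quality = "".join(chr(q + 33) for q in phred)
            if format == "collapsed-fasta":
                header = rec.description if rec.description else rec.id
                name, count = _parse_collapsed_header(header)
                records.append(SequenceRecord(name, seq, quality, count))
            else:
                records.append(SequenceRecord(rec.id, seq, quality))
    except ValueError as exc:  # Biopython parse failures
        raise ParseError(f"{path}: {exc}") from exc
    return records


def collapse_tags(
    records: Iterable[SequenceRecord], rna: bool = True
) -> list[SmallRNATag]:
    """Collapse reads into unique tags with redundant counts.

    One tag per distinct sequence; a record's carried count (collapsed
    input) is honoured, so the sum of tag counts equals the total input
    read count exactly.  Tags are ordered by descending count, then
    sequence, and named ``tag1..tagN`` in that order.
    """
    counts: dict[str, int] = {}
    for rec in records:
        seq = to_rna(rec.sequence) if rna else rec.sequence.upper()
        counts[seq] = counts.get(seq, 0) + rec.count
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRNATag(sequence=seq, count=n, id=f"tag{i + 1}")
        for i, (seq, n) in enumerate(ordered)
    ]


def expand_tags(tags: Iterable[SmallRNATag]) -> Iterator[str]:
    """Inverse of collapsing: yield each sequence ``count`` times."""
    for tag in tags:
        for _ in range(tag.count):
            yield tag.sequence


def write_collapsed_fasta(tags: Iterable[SmallRNATag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.id}_x{tag.count}\n{tag.sequence}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_tabular(report: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a header row.

    Row order is whatever the producing stage documented; this writer never
    re-sorts.
    """
    report.to_csv(path, sep="\t", index=False)


def read_tabular(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
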