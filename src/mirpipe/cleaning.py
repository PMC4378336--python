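"""Raw-read cleaning: contaminant classification and the cleaning summary.

Raw small-RNA reads are first gated on mean base quality (reads below the
gate are "low quality" and excluded from the 100% baseline), then assigned
to exactly one of five mutually exclusive contaminant categories, in fixed
precedence order:

1. ``3_adapter_null``       — no 3' adapter found anywhere in the read
2. ``insert_null``          — empty insert after adapter trimming
3. ``5_adapter_contaminant``— a 5'-adapter seed inside the insert
4. ``smaller_than_min``     — trimmed insert shorter than ``min_len``
5. ``poly_a``               — insert with A-fraction >= ``polya_frac``

Everything else with insert length <= ``max_len`` is clean; over-length
inserts are excluded but reported outside the five categories.  Category
counts always partition the high-quality total, and percentages are
computed against it (2 decimals, half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .io import SequenceRecord, SmallRNATag, collapse_tags, to_rna

__all__ = [
    "CleaningParams",
    "CleaningReport",
    "CATEGORY_LABELS",
    "classify_read",
    "clean_library",
    "size_distribution",
]

# Categories in Table-style report order; precedence order is the same.
CATEGORIES = (
    "3_adapter_null",
    "insert_null",
    "5_adapter_contaminant",
    "smaller_than_min",
    "poly_a",
)

# Human-readable row labels used in the TSV report.
CATEGORY_LABELS = {
    "3_adapter_null": "3' adapter_null",
    "insert_null": "Insert_null",
    "5_adapter_contaminant": "5' adapter_contaminants",
    "smaller_than_min": "Smaller_than_18 nt",
    "poly_a": "Poly A",
}


@dataclass(frozen=True)
class CleaningParams:
    """Knobs for the cleaning stage.

    ``adapter3``/``adapter5`` are the ligation adapters (any alphabet; they
    are normalised to RNA internally).  Adapter hits are seed matches of
    ``adapter_seed`` nt allowing ``adapter_max_mismatch`` mismatches,
    scanned 5'->3'; trimming happens at the leftmost hit.
    """

    adapter3: str = "UGGAAUUCUCGGGUGCCAAGG"
    adapter5: str = "GUUCAGAGUUCUACAGUCCGACGAUC"
    min_len: int = 18
    max_len: int = 30
    polya_frac: float = 0.9
    adapter_seed: int = 8
    adapter_max_mismatch: int = 1
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0 < self.polya_frac <= 1:
            raise ValueError("polya_frac must be in (0, 1]")


def _round2(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CleaningReport:
    """Per-category counts and percentages of the cleaning stage."""

    total_reads: int
    high_quality: int
    category_counts: dict[str, int]
    clean_reads: int
    over_length: int = 0

    def __post_init__(self) -> None:
        got = self.clean_reads + self.over_length + sum(self.category_counts.values())
        if got != self.high_quality:
            raise ValueError(
                f"category counts + clean ({got}) do not partition "
                f"high_quality ({self.high_quality})"
            )

    @classmethod
    def from_counts(
        cls,
        high_quality: int,
        category_counts: dict[str, int],
        total_reads: int | None = None,
        over_length: int = 0,
    ) -> "CleaningReport":
        clean = high_quality - over_length - sum(category_counts.values())
        return cls(
            total_reads=total_reads if total_reads is not None else high_quality,
            high_quality=high_quality,
            category_counts=dict(category_counts),
            clean_reads=clean,
            over_length=over_length,
        )

    def percent(self, count: int) -> float:
        if self.high_quality == 0:
            return 0.0
        return _round2(100.0 * count / self.high_quality)

    @property
    def clean_percent(self) -> float:
        return self.percent(self.clean_reads)

    def to_frame(self) -> pd.DataFrame:
        """Cleaning-summary table: one row per type, counts and percent."""
        rows = [
            ("Total_reads", self.total_reads, ""),
            ("High_quality", self.high_quality, "100%"),
        ]
        for cat in CATEGORIES:
            n = self.category_counts.get(cat, 0)
            rows.append((CATEGORY_LABELS[cat], n, f"{self.percent(n):.2f}%"))
        rows.append(("Clean_reads", self.clean_reads, f"{self.clean_percent:.2f}%"))
        return pd.DataFrame(rows, columns=["Type", "Count", "Percent"])


def _seed_find(haystack: str, seed: str, max_mismatch: int) -> int:
    """Leftmost position where ``seed`` matches with <= max_mismatch
    substitutions; -1 if none."""
    k = len(seed)
    if k == 0 or len(haystack) < k:
        return -1
    for i in range(len(haystack) - k + 1):
        mism = 0
        window = haystack[i : i + k]
        for a, b in zip(window, seed):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def classify_read(
    record: SequenceRecord, params: CleaningParams
) -> tuple[str, str | None]:
    """Assign one cleaning category to a quality-passing read.

    Returns ``(category, trimmed_insert)``; the insert is only meaningful
    for ``clean`` (and is the would-be insert for contaminant classes).
    """
    seq = to_rna(record.sequence)
    a3_seed = to_rna(params.adapter3)[: params.adapter_seed]
    a5_seed = to_rna(params.adapter5)[: params.adapter_seed]

    if not a3_seed:  # pre-trimmed library: the read is the insert
        insert = seq
    else:
        pos = _seed_find(seq, a3_seed, params.adapter_max_mismatch)
        if pos < 0:
            return "3_adapter_null", None
        insert = seq[:pos]
    if not insert:
        return "insert_null", None
    if _seed_find(insert, a5_seed, params.adapter_max_mismatch) >= 0:
        return "5_adapter_contaminant", insert
    if len(insert) < params.min_len:
        return "smaller_than_min", insert
    if insert.count("A") / len(insert) >= params.polya_frac:
        return "poly_a", insert
    if len(insert) > params.max_len:
        return "over_length", insert
    return "clean", insert


def clean_library(
    records: Sequence[SequenceRecord], params: CleaningParams | None = None
) -> tuple[list[SmallRNATag], CleaningReport]:
    """Run the full cleaning stage: quality gate, classify, trim, collapse."""
    params = params or CleaningParams()
    total = 0
    high_quality = 0
    counts = {cat: 0 for cat in CATEGORIES}
    over_length = 0
    clean_inserts: list[SequenceRecord] = []
    for rec in records:
        total += rec.count
        mq = rec.mean_quality()
        if mq is not None and mq < params.min_mean_quality:
            continue  # low quality: outside the 100% baseline
        high_quality += rec.count
        category, insert = classify_read(rec, params)
        if category == "clean":
            clean_inserts.append(
                SequenceRecord(rec.id, insert, None, rec.count)  # type: ignore[arg-type]
            )
        elif category == "over_length":
            over_length += rec.count
        else:
            counts[category] += rec.count
    clean_count = sum(r.count for r in clean_inserts)
    report = CleaningReport(
        total_reads=total,
        high_quality=high_quality,
        category_counts=counts,
        clean_reads=clean_count,
        over_length=over_length,
    )
    tags = collapse_tags(clean_inserts) if clean_inserts else []
    return tags, report


def size_distribution(tags: Iterable[SmallRNATag]) -> pd.DataFrame:
    """Length histogram weighted by redundant counts.

    Percentages are computed on redundant read counts and sum to 100%
    over the observed lengths.  Rows ordered by length.
    """
    weights: dict[int, int] = {}
    for tag in tags:
        weights[len(tag)] = weights.get(len(tag), 0) + tag.count
    total = sum(weights.values())
    rows = [
        (length, n, _round2(100.0 * n / total) if total else 0.0)
        for length, n in sorted(weights.items())
    ]
    return pd.DataFrame(rows, columns=["length", "count", "percent"])
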