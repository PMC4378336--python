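"""Rule-based plant miRNA target prediction.

Each transcript window of miRNA length is scored as an ungapped,
antiparallel duplex (miRNA position 1 = its 5' end) and accepted only when
all six plant-targeting rules hold:

i.   total mismatch score <= 4 (a G:U wobble counts 0.5);
ii.  no more than 2 contiguous full mismatches;
iii. no full mismatch in positions 2-12 (5' region); G:U wobbles are
     tolerated there subject to rule v — the strict reading, with no
     wobble tolerance in 2-12, is available as ``strict_five_prime``;
iv.  positions 10-11 perfectly matched (a wobble violates by default);
v.   mismatch score over positions 1-12 <= 2.5;
vi.  duplex energy >= 74% of the energy of the miRNA bound to its perfect
     complement (energies are negative; the ratio is a percentage).

Overlapping passing windows of one miRNA on one transcript collapse to the
best (lowest mismatch score, then lowest energy).  Reported coordinates are
1-based inclusive on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .folding import (
    EnergyModel,
    default_model,
    duplex_mfe,
    duplex_pair_states,
    perfect_complement_mfe,
)
from .io import SequenceRecord, to_rna

__all__ = [
    "TargetDuplex",
    "TargetThresholds",
    "score_duplex",
    "apply_rules",
    "scan_transcriptome",
    "target_report",
]

RULES = ("i", "ii", "iii", "iv", "v", "vi")


@dataclass(frozen=True)
class TargetThresholds:
    max_score: float = 4.0
    max_contiguous: int = 2
    five_prime_lo: int = 2  # rule iii window, 1-based inclusive
    five_prime_hi: int = 12
    seed_lo: int = 10  # rule iv positions
    seed_hi: int = 11
    max_five_prime_score: float = 2.5  # rule v over positions 1-12
    min_energy_ratio: float = 74.0  # percent
    strict_five_prime: bool = False  # rule iii intolerant of G:U in 2-12


@dataclass
class TargetDuplex:
    """A scored miRNA/transcript-site duplex."""

    mirna_name: str
    transcript_id: str
    site_start: int  # 1-based inclusive
    site_end: int
    pair_states: tuple[str, ...]  # per miRNA position, 5'->3'
    mismatch_score: float
    duplex_energy: float
    perfect_energy: float
    energy_ratio: float  # percent
    violations: tuple[str, ...] = ()

    @property
    def passes(self) -> bool:
        return not self.violations

    @property
    def cleavage_site(self) -> tuple[int, int]:
        """Transcript positions facing miRNA positions 10-11 (metadata)."""
        L = len(self.pair_states)
        return (self.site_start + L - 11, self.site_start + L - 10)


def mismatch_score(states: Sequence[str]) -> float:
    return sum(1.0 if s == "mismatch" else 0.5 if s == "GU" else 0.0 for s in states)


def score_duplex(
    mirna: str,
    site: str,
    mirna_name: str = "",
    transcript_id: str = "",
    site_start: int = 1,
    model: EnergyModel | None = None,
) -> TargetDuplex:
    """Score an ungapped duplex of a miRNA against an equal-length site.

    ``site`` is the transcript window in its natural 5'->3' orientation;
    pairing is antiparallel.  Scores and energies are filled; rules are
    applied separately by :func:`apply_rules`.
    """
    mirna = to_rna(mirna)
    site = to_rna(site)
    if len(mirna) != len(site):
        raise ValueError("site length must equal miRNA length")
    model = model or default_model()
    states = tuple(duplex_pair_states(mirna, site))
    energy = duplex_mfe(mirna, site, states, model)
    perfect = perfect_complement_mfe(mirna, model)
    ratio = 100.0 * energy / perfect if perfect < 0 else 0.0
    return TargetDuplex(
        mirna_name=mirna_name,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + len(mirna) - 1,
        pair_states=states,
        mismatch_score=mismatch_score(states),
        duplex_energy=energy,
        perfect_energy=perfect,
        energy_ratio=ratio,
    )


def apply_rules(
    duplex: TargetDuplex, thresholds: TargetThresholds | None = None
) -> list[str]:
    """Evaluate all six rules; returns every violated rule (empty = pass)."""
    th = thresholds or TargetThresholds()
    states = duplex.pair_states
    violations: list[str] = []

    if duplex.mismatch_score > th.max_score:
        violations.append("i")

    run = longest = 0
    for s in states:
        run = run + 1 if s == "mismatch" else 0
        longest = max(longest, run)
    if longest > th.max_contiguous:
        violations.append("ii")

    five_prime = states[th.five_prime_lo - 1 : th.five_prime_hi]
    if th.strict_five_prime:
        bad = any(s != "match" for s in five_prime)
    else:
        bad = any(s == "mismatch" for s in five_prime)
    if bad:
        violations.append("iii")

    if any(s != "match" for s in states[th.seed_lo - 1 : th.seed_hi]):
        violations.append("iv")

    if mismatch_score(states[:th.five_prime_hi]) > th.max_five_prime_score:
        violations.append("v")

    if duplex.energy_ratio < th.min_energy_ratio:
        violations.append("vi")

    duplex.violations = tuple(violations)
    return violations


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Sequence[SequenceRecord],
    thresholds: TargetThresholds | None = None,
    model: EnergyModel | None = None,
) -> list[TargetDuplex]:
    """Scan every window of miRNA length on each transcript for passing sites.

    Overlapping passes of one miRNA on one transcript are collapsed to the
    best (lowest mismatch score, then lowest duplex energy, then leftmost).
    """
    th = thresholds or TargetThresholds()
    model = model or default_model()
    passing: list[TargetDuplex] = []
    for name, mirna in mirnas.items():
        mirna = to_rna(mirna)
        L = len(mirna)
        perfect = perfect_complement_mfe(mirna, model)
        for rec in transcripts:
            seq = to_rna(rec.sequence)
            hits: list[TargetDuplex] = []
            for start in range(0, len(seq) - L + 1):
                states = tuple(duplex_pair_states(mirna, seq[start : start + L]))
                score = mismatch_score(states)
                if score > th.max_score:
                    continue  # rule i already fails; skip energy evaluation
                dup = TargetDuplex(
                    mirna_name=name,
                    transcript_id=rec.id,
                    site_start=start + 1,
                    site_end=start + L,
                    pair_states=states,
                    mismatch_score=score,
                    duplex_energy=duplex_mfe(mirna, seq[start : start + L], states, model),
                    perfect_energy=perfect,
                    energy_ratio=0.0,
                )
                dup.energy_ratio = (
                    100.0 * dup.duplex_energy / perfect if perfect < 0 else 0.0
                )
                if not apply_rules(dup, th):
                    hits.append(dup)
            # collapse overlapping hits to the best one
            hits.sort(key=lambda d: (d.mismatch_score, d.duplex_energy, d.site_start))
            chosen: list[TargetDuplex] = []
            for dup in hits:
                if all(
                    dup.site_end < c.site_start or dup.site_start > c.site_end
                    for c in chosen
                ):
                    chosen.append(dup)
            passing.extend(sorted(chosen, key=lambda d: d.site_start))
    return passing


def target_report(
    duplexes: Iterable[TargetDuplex],
    annotation: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Target table: miRNA, targets number, accession, annotation,
    location (1-based inclusive), free energy with bracketed ratio."""
    by_mirna: dict[str, list[TargetDuplex]] = {}
    for dup in duplexes:
        by_mirna.setdefault(dup.mirna_name, []).append(dup)
    rows = []
    for name in sorted(by_mirna):
        hits = by_mirna[name]
        for dup in hits:
            note = annotation.get(dup.transcript_id, "") if annotation else ""
            rows.append(
                (
                    name,
                    len(hits),
                    dup.transcript_id,
                    note,
                    f"{dup.site_start}, {dup.site_end}",
                    f"{dup.duplex_energy:.2f} [{dup.energy_ratio:.2f}%]",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "targets_number",
            "target_accession",
            "annotation",
            "location",
            "free_energy",
        ],
    )


def annotation_summary(
    duplexes: Iterable[TargetDuplex], annotation: Mapping[str, str]
) -> pd.DataFrame:
    """Generic category-count summary of targeted transcripts (a plain
    annotation join; no ontology logic)."""
    seen: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    for dup in duplexes:
        cat = annotation.get(dup.transcript_id, "unannotated")
        key = (cat, dup.transcript_id)
        if key not in seen:
            seen.add(key)
            counts[cat] = counts.get(cat, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["category", "n_targets"])
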