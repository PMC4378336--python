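"""Novel miRNA discovery from unannotated tags.

Unannotated tags are mapped exactly to the reference genome (both strands),
candidate precursor windows are excised around each locus, folded, and
accepted only when all five hairpin criteria hold:

i.   the tag maps exactly to the (unannotated part of the) genome;
ii.  the mature sits entirely in one arm of the hairpin;
iii. a star sequence — the pairing partner offset to leave 2-nt 3'
     overhangs on both strands (Dicer geometry) — fits inside the stem;
iv.  the mature/star duplex region has enough base pairs and no large
     bulge or internal loop (defaults: >= 16 pairs, no loop > 4 nt);
v.   the hairpin is stable: MFE <= -20 kcal/mol.

Every failed criterion is reported, not just the first.  Expression of an
accepted novel miRNA sums the counts of tags that differ from the mature
only within the terminal 3 nt at either end (exact middle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .folding import EnergyModel, SecondaryStructure, default_model, fold_hairpin
from .io import SequenceRecord, SmallRNATag, revcomp_rna, to_rna

__all__ = [
    "GenomicLocus",
    "HairpinCandidate",
    "NovelThresholds",
    "map_and_excise",
    "evaluate_candidate",
    "check_criteria",
    "quantify_novel",
    "discover_novel",
]

CRITERIA = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class NovelThresholds:
    """Quantified hairpin criteria.

    ``mfe_max`` is the stability bound (criterion v, inclusive);
    ``min_pairs``/``max_bulge`` quantify "no large internal loops or
    bulges" in the mature/star duplex region (criterion iv).
    """

    mfe_max: float = -20.0
    min_pairs: int = 16
    max_bulge: int = 4
    flank_up: int = 20
    flank_down: int = 250
    max_loci: int = 20


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    tag: SmallRNATag

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid locus coordinates")
        if self.end - self.start != len(self.tag.sequence):
            raise ValueError("locus span must equal tag length")


@dataclass
class HairpinCandidate:
    """A folded precursor window with its criteria record."""

    precursor: str
    structure: SecondaryStructure
    mature_span: tuple[int, int]  # 0-based half-open on precursor
    star_span: tuple[int, int] | None
    arm: str | None  # 5p | 3p
    mfe: float
    pairs_in_duplex: int
    max_bulge: int
    criteria_flags: dict[str, bool]
    locus: GenomicLocus | None = None
    name: str = ""

    @property
    def accepted(self) -> bool:
        return all(self.criteria_flags.values())

    @property
    def failed(self) -> list[str]:
        return [c for c in CRITERIA if not self.criteria_flags.get(c, True)]

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_span[0] : self.mature_span[1]]


def map_exact(
    tag: SmallRNATag, genome: Sequence[SequenceRecord]
) -> list[GenomicLocus]:
    """All exact-match loci of the tag on both strands of the genome."""
    loci: list[GenomicLocus] = []
    L = len(tag.sequence)
    for rec in genome:
        seq = to_rna(rec.sequence)
        for strand, needle in (("+", tag.sequence), ("-", revcomp_rna(tag.sequence))):
            pos = seq.find(needle)
            while pos >= 0:
                loci.append(GenomicLocus(rec.id, pos, pos + L, strand, tag))
                pos = seq.find(needle, pos + 1)
    return loci


def map_and_excise(
    tag: SmallRNATag,
    genome: Sequence[SequenceRecord],
    thresholds: NovelThresholds | None = None,
) -> list[tuple[GenomicLocus, str]]:
    """Excise candidate precursor windows around each exact-match locus.

    For every locus two windows are cut — tag near the 5' end with a long
    3' flank, and the mirror image — clipped at contig ends, so a mature on
    either hairpin arm is covered.  Windows are returned in genome (+
    strand tag) orientation, i.e. already reverse-complemented for minus-
    strand loci.  Tags hitting more than ``max_loci`` places are treated as
    repeat-derived and skipped (empty result).
    """
    th = thresholds or NovelThresholds()
    loci = map_exact(tag, genome)
    if len(loci) > th.max_loci:
        return []
    genome_by_id = {rec.id: to_rna(rec.sequence) for rec in genome}
    out: list[tuple[GenomicLocus, str]] = []
    for locus in loci:
        seq = genome_by_id[locus.chrom]
        if locus.strand == "+":
            geometries = (
                (locus.start - th.flank_up, locus.end + th.flank_down),
                (locus.start - th.flank_down, locus.end + th.flank_up),
            )
        else:
            geometries = (
                (locus.start - th.flank_down, locus.end + th.flank_up),
                (locus.start - th.flank_up, locus.end + th.flank_down),
            )
        for lo, hi in geometries:
            lo = max(0, lo)
            hi = min(len(seq), hi)
            window = seq[lo:hi]
            if locus.strand == "-":
                window = revcomp_rna(window)
            out.append((locus, window))
    return out


def _runs_of_unpaired(
    pm: dict[int, int], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Maximal runs of unpaired positions within [lo, hi)."""
    runs = []
    start = None
    for p in range(lo, hi):
        if p not in pm:
            if start is None:
                start = p
        elif start is not None:
            runs.append((start, p))
            start = None
    if start is not None:
        runs.append((start, hi))
    return runs


def check_criteria(
    mfe: float,
    in_one_arm: bool,
    star_found: bool,
    pairs_in_duplex: int,
    max_bulge_seen: int,
    thresholds: NovelThresholds | None = None,
) -> dict[str, bool]:
    """Evaluate criteria ii-v from their measured quantities.

    Criterion i (exact genome match of an unannotated tag) is established
    upstream by the mapping stage and always True here.
    """
    th = thresholds or NovelThresholds()
    return {
        "i": True,
        "ii": in_one_arm,
        "iii": star_found,
        "iv": pairs_in_duplex >= th.min_pairs and max_bulge_seen <= th.max_bulge,
        "v": mfe <= th.mfe_max,
    }


def evaluate_candidate(
    window: str,
    tag: SmallRNATag,
    model: EnergyModel | None = None,
    thresholds: NovelThresholds | None = None,
    locus: GenomicLocus | None = None,
) -> HairpinCandidate:
    """Fold a precursor window and score the five hairpin criteria.

    The window must contain the tag exactly once.  All criteria are
    evaluated; the returned candidate records every failure.
    """
    th = thresholds or NovelThresholds()
    model = model or default_model()
    window = to_rna(window)
    mature = tag.sequence
    first = window.find(mature)
    if first < 0 or window.find(mature, first + 1) >= 0:
        raise ValueError("window must contain the tag exactly once")
    m_lo, m_hi = first, first + len(mature)

    structure = fold_hairpin(window, model)
    pm = structure.pair_map()

    # Arm call (criterion ii): the terminal loop of the stem separates the
    # arms; the mature must not straddle it.
    in_one_arm = False
    arm: str | None = None
    if structure.pairs:
        innermost = max(structure.pairs, key=lambda p: p[0])  # deepest pair
        loop_lo, loop_hi = innermost[0], innermost[1]  # loop is (lo, hi) exclusive
        if m_hi - 1 <= loop_lo:
            in_one_arm = True
            arm = "5p"
        elif m_lo >= loop_hi:
            in_one_arm = True
            arm = "3p"

    # Star span (criterion iii): partner of the mature with 2-nt 3'
    # overhangs on both strands.
    star_span: tuple[int, int] | None = None
    if in_one_arm:
        partners = [pm[p] for p in range(m_lo, m_hi) if p in pm]
        if partners:
            lo_p, hi_p = min(partners), max(partners)
            star_lo, star_hi = lo_p + 2, hi_p + 2 + 1
            if 0 <= star_lo < star_hi <= len(window):
                overlap = not (star_hi <= m_lo or star_lo >= m_hi)
                if not overlap:
                    star_span = (star_lo, star_hi)

    # Duplex-region quality (criterion iv): pairs of the mature itself and
    # loop/bulge sizes inside mature or star.
    pairs_in_duplex = sum(1 for p in range(m_lo, m_hi) if p in pm)
    max_bulge_seen = 0
    regions = [(m_lo, m_hi)]
    if star_span is not None:
        regions.append(star_span)
    for lo, hi in regions:
        for rs, re_ in _runs_of_unpaired(pm, lo, hi):
            # terminal overhangs of the star are by-construction unpaired
            if star_span is not None and (lo, hi) == star_span:
                if re_ == star_span[1] and re_ - rs <= 2:
                    continue
            max_bulge_seen = max(max_bulge_seen, re_ - rs)

    flags = check_criteria(
        structure.mfe, in_one_arm, star_span is not None,
        pairs_in_duplex, max_bulge_seen, th,
    )
    return HairpinCandidate(
        precursor=window,
        structure=structure,
        mature_span=(m_lo, m_hi),
        star_span=star_span,
        arm=arm,
        mfe=structure.mfe,
        pairs_in_duplex=pairs_in_duplex,
        max_bulge=max_bulge_seen,
        criteria_flags=flags,
        locus=locus,
    )


def _middle_core(seq: str, end_tolerance: int = 3) -> str:
    return seq[end_tolerance:-end_tolerance]


def quantify_novel(
    candidate: HairpinCandidate,
    tags: Iterable[SmallRNATag],
    end_tolerance: int = 3,
) -> int:
    """Expression of an accepted candidate.

    Sums counts of tags whose sequence matches the mature exactly over the
    middle region, with differences (trims, extensions, substitutions)
    confined to the terminal ``end_tolerance`` nt at either end.
    """
    if not candidate.accepted:
        raise ValueError("quantify_novel requires an accepted candidate")
    mature = candidate.mature
    core = _middle_core(mature, end_tolerance)
    core_pos_in_mature = end_tolerance
    total = 0
    for tag in tags:
        idx = tag.sequence.find(core)
        if idx < 0:
            continue
        # The core anchors the alignment; flanks must fit in the tolerance.
        left_tag = tag.sequence[:idx]
        right_tag = tag.sequence[idx + len(core):]
        if len(left_tag) > end_tolerance or len(right_tag) > end_tolerance:
            continue
        total += tag.count
    return total


def discover_novel(
    tags: Sequence[SmallRNATag],
    genome: Sequence[SequenceRecord],
    model: EnergyModel | None = None,
    thresholds: NovelThresholds | None = None,
    name_prefix: str = "col-miRN",
) -> list[HairpinCandidate]:
    """Full novel stage: map, excise, evaluate; keep the best accepted
    candidate per tag, one candidate per genomic hairpin locus (isomiR
    variants of an already-called mature collapse onto it), named
    ``col-miRN<k>-<arm>`` in order of decreasing mature count."""
    th = thresholds or NovelThresholds()
    model = model or default_model()
    accepted: list[HairpinCandidate] = []
    taken: list[GenomicLocus] = []
    for tag in sorted(tags, key=lambda t: (-t.count, t.sequence)):
        best: HairpinCandidate | None = None
        for locus, window in map_and_excise(tag, genome, th):
            if any(
                locus.chrom == t.chrom
                and locus.start < t.end + th.flank_down
                and t.start < locus.end + th.flank_down
                for t in taken
            ):
                continue  # hairpin already called from a higher-count tag
            if window.count(tag.sequence) != 1:
                continue
            cand = evaluate_candidate(window, tag, model, th, locus)
            if cand.accepted and (best is None or cand.mfe < best.mfe):
                best = cand
        if best is not None:
            accepted.append(best)
            assert best.locus is not None
            taken.append(best.locus)
    for k, cand in enumerate(accepted, start=1):
        cand.name = f"{name_prefix}{k}-{cand.arm}"
    return accepted


def novel_report(
    candidates: Sequence[HairpinCandidate],
    tags: Sequence[SmallRNATag],
) -> pd.DataFrame:
    """Novel-miRNA table: name, reads, mature sequence, length, MFE."""
    rows = []
    for cand in candidates:
        rows.append(
            (
                cand.name,
                quantify_novel(cand, tags),
                cand.mature,
                len(cand.mature),
                round(cand.mfe, 2),
            )
        )
    return pd.DataFrame(
        rows, columns=["name", "reads", "mature_sequence", "length", "mfe_kcal_mol"]
    )


def loci_to_gff3(candidates: Sequence[HairpinCandidate]) -> str:
    """GFF3 rendering of accepted precursor loci."""
    lines = ["##gff-version 3"]
    for cand in candidates:
        if cand.locus is None:
            continue
        loc = cand.locus
        lines.append(
            "\t".join(
                [
                    loc.chrom,
                    "mirpipe",
                    "miRNA_primary_transcript",
                    str(loc.start + 1),
                    str(loc.end),
                    f"{cand.mfe:.2f}",
                    loc.strand,
                    ".",
                    f"ID={cand.name};arm={cand.arm}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
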