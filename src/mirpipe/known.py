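"""Known-miRNA annotation: ncRNA exclusion, database assignment within a
mismatch budget, family grouping/quantification, and conservation calls.

Assignment follows the small-RNA convention of aligning each tag end-to-end
against every mature entry of a miRBase-style database and accepting the
best hit when its combined edit cost (substitutions + gaps, terminal gaps
included) is within a budget of 3.  Families are keyed by the miR-number
token of the best hit's name; family expression is the summed redundant
count of every tag that aligns to the family's most-expressed member (the
representative) within the same budget, each tag counting toward at most
one representative.

A family is called conserved when it is present in at least
``conservation_min`` (default 9) plant species of a presence table;
non-conserved families split into "defined" (their miR number appears in
the table) and "undefined".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord, SmallRNATag, to_rna

__all__ = [
    "KnownMiRNAHit",
    "MiRNAFamily",
    "align_with_budget",
    "filter_ncrna",
    "assign_known",
    "group_and_quantify",
    "classify_conservation",
    "parse_mirna_name",
    "DEFAULT_FAMILY_ALIASES",
]

# Classic plant family merges: the database annotates these numerals as
# members of one family (e.g. miR157 matures sit in the miR156 family).
DEFAULT_FAMILY_ALIASES: Mapping[str, str] = {
    "miR157": "miR156",
    "miR165": "miR166",
}

_NAME_RE = re.compile(
    r"^(?P<species>[a-zA-Z]{3,4})-(?P<family>miR|MIR)(?P<number>\d+)(?P<suffix>.*)$"
)


def parse_mirna_name(name: str) -> tuple[str, str, str] | None:
    """Split ``ath-miR157a-5p`` into (species, family token, rest).

    Returns (``ath``, ``miR157``, ``miR157a-5p``); None when the name does
    not follow the ``xxx-miRNNNsuffix`` convention.
    """
    m = _NAME_RE.match(name)
    if not m:
        return None
    family = "miR" + m.group("number")
    rest = m.group("family") + m.group("number") + m.group("suffix")
    return m.group("species"), family, rest


@dataclass(frozen=True)
class KnownMiRNAHit:
    """A tag assigned to a database mature miRNA."""

    tag: SmallRNATag
    db_name: str
    matches: int
    mismatches: int
    gaps: int
    assigned_name: str

    @property
    def distance(self) -> int:
        return self.mismatches + self.gaps


@dataclass
class MiRNAFamily:
    """A mature-miRNA family with its representative and summed expression."""

    family_id: str
    members: list[KnownMiRNAHit]
    representative: KnownMiRNAHit
    expression: int
    conserved_flag: bool | None = None
    species_presence: int | None = None
    conservation_class: str | None = None


def align_with_budget(
    query: str, reference: str, max_dist: int = 3
) -> tuple[int, int, int] | None:
    """Minimum-cost end-to-end alignment with unit substitution/gap costs.

    Returns ``(matches, mismatches, gaps)`` of the optimal alignment, or
    None when the minimum ``mismatches + gaps`` exceeds ``max_dist``.
    Terminal gaps cost 1 like any other gap.  Ties on cost are broken
    toward more matches, then fewer gaps.
    """
    if not query or not reference:
        raise ValueError("align_with_budget requires non-empty sequences")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    q = to_rna(query)
    r = to_rna(reference)
    n, m = len(q), len(r)
    if abs(n - m) > max_dist:
        return None
    # DP over (cost, -matches, gaps): lexicographic min is well defined
    # because every transition adds a non-negative triple.
    INF = (10**9, 0, 0)
    prev = [(j, 0, j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [INF] * (m + 1)
        cur[0] = (i, 0, i)
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == r[j - 1]:
                c, neg, g = prev[j - 1]
                best = (c, neg - 1, g)
            else:
                c, neg, g = prev[j - 1]
                best = (c + 1, neg, g)
            c, neg, g = prev[j]  # gap in reference
            cand = (c + 1, neg, g + 1)
            if cand < best:
                best = cand
            c, neg, g = cur[j - 1]  # gap in query
            cand = (c + 1, neg, g + 1)
            if cand < best:
                best = cand
            cur[j] = best
        prev = cur
    cost, neg_matches, gaps = prev[m]
    if cost > max_dist:
        return None
    matches = -neg_matches
    mismatches = cost - gaps
    return matches, mismatches, gaps


_NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "mRNA", "repeat")


def _ncrna_class(record_id: str) -> str:
    for cls in _NCRNA_CLASSES:
        if record_id.lower().startswith(cls.lower()):
            return cls
    return "other"


def filter_ncrna(
    tags: Sequence[SmallRNATag],
    exclusion_set: Sequence[SequenceRecord],
    mode: str = "substring",
) -> tuple[list[SmallRNATag], dict[str, int]]:
    """Remove tags fully matching a non-miRNA ncRNA record.

    ``mode='substring'`` (default) removes a tag whose sequence occurs
    exactly inside any exclusion record ("fully matching" in the read
    sense); ``mode='equal'`` requires whole-record equality.  Returns the
    surviving tags and per-class removal counts (classes parsed from
    record-id prefixes such as ``rRNA_001``).
    """
    if mode not in {"substring", "equal"}:
        raise ValueError(f"unknown filter mode {mode!r}")
    removed: dict[str, int] = {}
    kept: list[SmallRNATag] = []
    ref = [(rec, to_rna(rec.sequence)) for rec in exclusion_set]
    for tag in tags:
        hit_class = None
        for rec, seq in ref:
            if (mode == "substring" and tag.sequence in seq) or (
                mode == "equal" and tag.sequence == seq
            ):
                hit_class = _ncrna_class(rec.id)
                break
        if hit_class is None:
            kept.append(tag)
        else:
            removed[hit_class] = removed.get(hit_class, 0) + tag.count
    return kept, removed


def assign_known(
    tags: Sequence[SmallRNATag],
    database: Sequence[SequenceRecord],
    max_dist: int = 3,
    species_prefix: str = "col",
) -> tuple[list[KnownMiRNAHit], list[SmallRNATag]]:
    """Assign each tag to its best database mature within the edit budget.

    Best hit = minimum ``mismatches + gaps``; ties go to the database entry
    with the larger exact-match usage (total count of tags identical to
    it), then to the lexicographically smaller name.  The assigned pipeline
    name replaces the database species prefix with ``species_prefix``.
    Returns (hits, unassigned tags) — the unassigned flow to novel
    discovery.
    """
    entries: list[tuple[str, str, str]] = []  # (name, seq, family)
    for rec in database:
        parsed = parse_mirna_name(rec.id)
        if parsed is None:
            warnings.warn(f"skipping unparseable database name {rec.id!r}")
            continue
        entries.append((rec.id, to_rna(rec.sequence), parsed[1]))

    exact_usage: dict[str, int] = {name: 0 for name, _, _ in entries}
    tag_by_seq: dict[str, int] = {}
    for tag in tags:
        tag_by_seq[tag.sequence] = tag_by_seq.get(tag.sequence, 0) + tag.count
    for name, seq, _ in entries:
        exact_usage[name] = tag_by_seq.get(seq, 0)

    hits: list[KnownMiRNAHit] = []
    unassigned: list[SmallRNATag] = []
    for tag in tags:
        best: tuple[tuple[int, int, str], tuple[int, int, int], str] | None = None
        for name, seq, _family in entries:
            aln = align_with_budget(tag.sequence, seq, max_dist)
            if aln is None:
                continue
            matches, mismatches, gaps = aln
            key = (mismatches + gaps, -exact_usage[name], name)
            if best is None or key < best[0]:
                best = (key, aln, name)
        if best is None:
            unassigned.append(tag)
            continue
        _, (matches, mismatches, gaps), name = best
        parsed = parse_mirna_name(name)
        assert parsed is not None
        assigned = f"{species_prefix}-{parsed[2]}"
        hits.append(
            KnownMiRNAHit(
                tag=tag,
                db_name=name,
                matches=matches,
                mismatches=mismatches,
                gaps=gaps,
                assigned_name=assigned,
            )
        )
    return hits, unassigned


def group_and_quantify(
    hits: Sequence[KnownMiRNAHit],
    tags: Sequence[SmallRNATag],
    max_dist: int = 3,
    family_aliases: Mapping[str, str] = DEFAULT_FAMILY_ALIASES,
) -> list[MiRNAFamily]:
    """Group hits into families and quantify family expression.

    Families are keyed by the miR-number token of the best hit (with
    alias merging, e.g. miR157 -> miR156).  The representative is the
    highest-count member; expression sums the counts of every tag aligning
    to the representative within the budget, each tag contributing to at
    most one family (ties: family whose representative has the higher
    count, then lexicographic family id).
    """
    groups: dict[str, list[KnownMiRNAHit]] = {}
    for hit in hits:
        parsed = parse_mirna_name(hit.db_name)
        family = parsed[1] if parsed else hit.db_name
        family = family_aliases.get(family, family)
        groups.setdefault(family, []).append(hit)

    families: list[MiRNAFamily] = []
    for family_id, members in sorted(groups.items()):
        rep = max(members, key=lambda h: (h.tag.count, h.tag.sequence))
        families.append(
            MiRNAFamily(
                family_id=family_id, members=members, representative=rep, expression=0
            )
        )

    # Each tag counts toward at most one representative.
    order = sorted(
        families, key=lambda f: (-f.representative.tag.count, f.family_id)
    )
    for tag in tags:
        for fam in order:
            if align_with_budget(
                tag.sequence, fam.representative.tag.sequence, max_dist
            ) is not None:
                fam.expression += tag.count
                break
    return families


def classify_conservation(
    family: MiRNAFamily,
    presence_table: pd.DataFrame,
    threshold: int = 9,
) -> str:
    """Call a family conserved / nonconserved-defined / nonconserved-undefined.

    ``presence_table`` is species x family booleans.  Conserved iff the
    family is present in >= ``threshold`` species; non-conserved families
    present in the table's columns are "defined", others "undefined".
    """
    if family.family_id in presence_table.columns:
        presence = int(presence_table[family.family_id].astype(bool).sum())
        family.species_presence = presence
        if presence >= threshold:
            cls = "conserved"
        else:
            cls = "nonconserved-defined"
    else:
        family.species_presence = 0
        cls = "nonconserved-undefined"
    family.conserved_flag = cls == "conserved"
    family.conservation_class = cls
    return cls


def family_report(families: Sequence[MiRNAFamily]) -> pd.DataFrame:
    """Per-family table mirroring the known-miRNA summary layout."""
    rows = []
    for fam in sorted(families, key=lambda f: -f.expression):
        rep = fam.representative
        rows.append(
            (
                fam.family_id,
                rep.assigned_name,
                len(rep.tag.sequence),
                rep.tag.count,
                rep.tag.sequence,
                rep.db_name,
                rep.matches,
                rep.mismatches,
                rep.gaps,
                fam.expression,
                len(fam.members),
                fam.conservation_class or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "mirna",
            "length",
            "count",
            "sequence",
            "homolog",
            "matches",
            "mismatches",
            "gaps",
            "family_expression",
            "members",
            "conservation",
        ],
    )
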