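"""Known-miRNA annotation: budgeted alignment, exclusion, assignment,
family quantification, conservation calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from mirpipe.io import SequenceRecord, SmallRNATag
from mirpipe.known import (
    MiRNAFamily,
    align_with_budget,
    assign_known,
    classify_conservation,
    filter_ncrna,
    group_and_quantify,
    parse_mirna_name,
)

MIR157A = "UUGACAGAAGAUAGAGAGCAC"
MIR156A = "UGACAGAAGAGAGUGAGCAC"

rna = st.text(alphabet="ACGU", min_size=1, max_size=25)


def test_identical_sequences_align_with_full_matches():
    assert align_with_budget(MIR157A, MIR157A) == (21, 0, 0)
    assert align_with_budget("ACGU", "ACGU", 0) == (4, 0, 0)


def test_family_paralogs_differ_by_three_edits():
    """The miR157a/miR156a pair sits exactly at the edit budget."""
    result = align_with_budget(MIR157A, MIR156A, 3)
    assert result is not None
    matches, mismatches, gaps = result
    assert mismatches + gaps == 3
    assert oracles.edit_distance(MIR157A, MIR156A) == 3


def test_no_hit_beyond_budget():
    assert align_with_budget("AAAAAAAAAAAAAAAAAAAAA", MIR157A, 3) is None


def test_empty_sequence_is_usage_error():
    with pytest.raises(ValueError):
        align_with_budget("", "ACGU")


@settings(deadline=None, max_examples=300, derandomize=True)
@given(rna, rna)
def test_alignment_cost_equals_edit_distance_oracle(a, b):
    dist = oracles.edit_distance(a, b)
    result = align_with_budget(a, b, max_dist=50)
    assert result is not None
    matches, mismatches, gaps = result
    assert mismatches + gaps == dist
    assert matches <= min(len(a), len(b))


def test_alignment_against_edlib():
    edlib = pytest.importorskip("edlib")
    rng = np.random.default_rng(21)
    for _ in range(200):
        a = "".join(rng.choice(list("ACGU"), size=int(rng.integers(15, 26))))
        b = "".join(rng.choice(list("ACGU"), size=int(rng.integers(15, 26))))
        result = align_with_budget(a, b, max_dist=60)
        assert result is not None
        _, mm, g = result
        assert mm + g == edlib.align(a, b, mode="NW")["editDistance"]


def test_filter_ncrna_substring_and_classes():
    tags = [
        SmallRNATag("ACGUACGUACGUACGUACGUA", 5, "t1"),
        SmallRNATag("GGGGCCCCGGGGCCCCGGGG", 2, "t2"),
    ]
    exclusion = [SequenceRecord("rRNA_1", "UU" + tags[0].sequence + "AA")]
    kept, removed = filter_ncrna(tags, exclusion)
    assert [t.id for t in kept] == ["t2"]
    assert removed == {"rRNA": 5}
    kept_eq, _ = filter_ncrna(tags, exclusion, mode="equal")
    assert len(kept_eq) == 2  # substring hit is not whole-record equality


def test_filter_ncrna_planted_mix_removed_exactly():
    rng = np.random.default_rng(4)
    rrna = ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(100)]
    mirna = ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(100)]
    tags = [SmallRNATag(s, 1, f"r{i}") for i, s in enumerate(rrna)]
    tags += [SmallRNATag(s, 1, f"m{i}") for i, s in enumerate(mirna)]
    exclusion = [
        SequenceRecord("rRNA_big", "".join(rrna))
    ]
    kept, removed = filter_ncrna(tags, exclusion)
    assert {t.sequence for t in kept} == set(mirna)
    assert removed["rRNA"] == 100


def test_name_parsing():
    assert parse_mirna_name("ath-miR157a") == ("ath", "miR157", "miR157a")
    assert parse_mirna_name("gma-miR396b-3p") == ("gma", "miR396", "miR396b-3p")
    assert parse_mirna_name("not_a_name") is None


def test_assignment_identity_and_prefix_rename():
    db = [SequenceRecord("ath-miR156a", MIR156A)]
    tags = [SmallRNATag(MIR156A, 100, "t1")]
    hits, unassigned = assign_known(tags, db)
    assert not unassigned
    (hit,) = hits
    assert (hit.matches, hit.mismatches, hit.gaps) == (20, 0, 0)
    assert hit.assigned_name == "col-miR156a"


def test_distance_four_is_unassigned():
    db = [SequenceRecord("ath-miR156a", MIR156A)]
    mutated = list(MIR156A)
    for pos in (2, 7, 12, 17):  # spread substitutions, gaps cannot rescue
        mutated[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[pos]]
    mutated = "".join(mutated)
    assert oracles.edit_distance(mutated, MIR156A) == 4
    hits, unassigned = assign_known([SmallRNATag(mutated, 1, "t1")], db)
    assert not hits and len(unassigned) == 1


def test_planted_mutated_matures_recover_their_families(study):
    """Database matures mutated by <= 3 edits are assigned back to the
    correct family (at least 19 of 20)."""
    tags = [
        SmallRNATag(k.planted_sequence, 10, f"t{i}")
        for i, k in enumerate(study.known_truth)
    ]
    hits, unassigned = assign_known(tags, study.known_db)
    correct = 0
    truth_by_seq = {k.planted_sequence: k.family for k in study.known_truth}
    for hit in hits:
        parsed = parse_mirna_name(hit.db_name)
        if parsed and parsed[1] == truth_by_seq[hit.tag.sequence]:
            correct += 1
    assert correct >= 19


def test_family_representative_is_highest_count():
    db = [
        SequenceRecord("ath-miR157a", MIR157A),
        SequenceRecord("ath-miR156a", MIR156A),
    ]
    tags = [
        SmallRNATag(MIR157A, 5_531_609, "t1"),
        SmallRNATag(MIR156A, 1_724_997, "t2"),
    ]
    hits, _ = assign_known(tags, db)
    families = group_and_quantify(hits, tags)
    (fam,) = families  # miR157 folds into the miR156 family
    assert fam.family_id == "miR156"
    assert fam.representative.assigned_name == "col-miR157a"
    assert fam.expression == 5_531_609 + 1_724_997


def test_single_member_family_expression_is_member_count():
    db = [SequenceRecord("ath-miR164a", "UGGAGAAGCAGGGCACGUGCA")]
    tags = [SmallRNATag("UGGAGAAGCAGGGCACGUGCA", 7491, "t1")]
    hits, _ = assign_known(tags, db)
    (fam,) = group_and_quantify(hits, tags)
    assert fam.expression == 7491


def test_family_expression_equals_recount_oracle():
    """Family expression equals an exhaustive re-count of tags within the
    budget of the representative."""
    rng = np.random.default_rng(17)
    base = "".join(rng.choice(list("ACGU"), size=21))
    variants = []
    for k in range(3):
        v = list(base)
        for p in rng.choice(21, size=k, replace=False):
            v[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[v[p]]
        variants.append("".join(v))
    db = [SequenceRecord("ath-miR800a", base)]
    tags = [
        SmallRNATag(v, int(c), f"t{i}")
        for i, (v, c) in enumerate(zip(variants, (50, 20, 10)))
    ]
    hits, _ = assign_known(tags, db)
    (fam,) = group_and_quantify(hits, tags)
    rep = fam.representative.tag.sequence
    oracle_sum = sum(
        t.count for t in tags if oracles.edit_distance(t.sequence, rep) <= 3
    )
    assert fam.expression == oracle_sum
    assert fam.expression <= sum(t.count for t in tags)


def _family(fid: str) -> MiRNAFamily:
    tag = SmallRNATag("ACGU" * 5 + "A", 10, "t")
    from mirpipe.known import KnownMiRNAHit

    hit = KnownMiRNAHit(tag, f"ath-{fid}a", 21, 0, 0, f"col-{fid}a")
    return MiRNAFamily(fid, [hit], hit, 10)


@pytest.mark.parametrize(
    "n_species,expected",
    [(9, "conserved"), (8, "nonconserved-defined")],
)
def test_conservation_boundary_at_nine_species(n_species, expected):
    table = pd.DataFrame(
        {"miR156": [True] * n_species + [False] * (12 - n_species)},
        index=[f"sp{i}" for i in range(12)],
    )
    fam = _family("miR156")
    assert classify_conservation(fam, table, threshold=9) == expected


def test_family_absent_from_table_is_undefined():
    table = pd.DataFrame({"miR156": [True] * 12})
    fam = _family("miR999")
    assert classify_conservation(fam, table) == "nonconserved-undefined"
    assert fam.conserved_flag is False
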