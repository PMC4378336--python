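"""Novel miRNA discovery: mapping, excision, hairpin criteria, expression."""

import numpy as np
import pytest

from mirpipe.io import SequenceRecord, SmallRNATag, revcomp_rna
from mirpipe.novel import (
    HairpinCandidate,
    NovelThresholds,
    check_criteria,
    discover_novel,
    evaluate_candidate,
    map_and_excise,
    map_exact,
    quantify_novel,
)
from mirpipe.simulate import SimulationConfig, simulate_genome_and_hairpins


def _rand(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(51)
    mature = _rand(rng, 21)
    arm = "GCAU" + mature + _rand(rng, 15)
    precursor = arm + _rand(rng, 12) + revcomp_rna(arm)
    genome_seq = _rand(rng, 400) + precursor + _rand(rng, 400)
    genome = [SequenceRecord("chr1", genome_seq)]
    tag = SmallRNATag(mature, 50, "t1")
    return genome, tag, precursor


def test_single_plus_strand_locus_gives_two_windows():
    """A tag planted once in plain background (no hairpin, so no star-arm
    mirror hit) yields one locus and two excision windows."""
    rng = np.random.default_rng(55)
    mature = _rand(rng, 21)
    genome = [SequenceRecord("chr1", _rand(rng, 500) + mature + _rand(rng, 500))]
    windows = map_and_excise(SmallRNATag(mature, 5, "t"), genome)
    assert len(windows) == 2
    for locus, window in windows:
        assert locus.strand == "+"
        assert mature in window


def test_hairpin_mature_maps_to_both_arms(planted):
    """In a perfect-stem hairpin the mature also matches the star arm on
    the minus strand, so excision sees two loci (four windows)."""
    genome, tag, _ = planted
    windows = map_and_excise(tag, genome)
    assert len(windows) == 4
    assert {loc.strand for loc, _ in windows} == {"+", "-"}


def test_absent_tag_has_no_loci():
    genome = [SequenceRecord("chr1", "ACGU" * 100)]
    assert map_exact(SmallRNATag("GGGGCCCCAAAAUUUUGGGGC", 1, "t"), genome) == []


def test_some_window_contains_whole_precursor(planted):
    genome, tag, precursor = planted
    windows = map_and_excise(tag, genome)
    assert any(precursor in w for _, w in windows)


def test_repeat_like_tag_skipped():
    unit = "UGGCAUGCAUCGUACGAUGCA"
    genome = [SequenceRecord("chr1", ("AACC" + unit) * 30)]
    tag = SmallRNATag(unit, 5, "t")
    assert map_and_excise(tag, genome) == []


def test_planted_ideal_hairpin_accepted(planted):
    genome, tag, _ = planted
    accepted = [
        evaluate_candidate(w, tag, locus=loc)
        for loc, w in map_and_excise(tag, genome)
        if w.count(tag.sequence) == 1
    ]
    best = [c for c in accepted if c.accepted]
    assert best
    assert best[0].arm == "5p"
    assert best[0].mfe <= -20.0
    assert best[0].star_span is not None


def test_tag_absent_from_window_is_usage_error():
    with pytest.raises(ValueError, match="exactly once"):
        evaluate_candidate("ACGU" * 30, SmallRNATag("GGGGGGGGGGGGGGGGGGGGG", 1, "t"))


def test_mfe_boundary_is_inclusive():
    flags = check_criteria(-20.0, True, True, 20, 0)
    assert flags["v"] is True
    flags = check_criteria(-19.5, True, True, 20, 0)
    assert flags["v"] is False and all(flags[c] for c in "i ii iii iv".split())


def test_large_bulge_fails_criterion_iv():
    flags = check_criteria(-50.0, True, True, 20, 6)
    assert flags["iv"] is False
    assert check_criteria(-50.0, True, True, 20, 4)["iv"] is True
    assert check_criteria(-50.0, True, True, 15, 0)["iv"] is False  # few pairs


def test_mature_straddling_loop_rejected():
    rng = np.random.default_rng(53)
    stem = _rand(rng, 25)
    mature = stem[-8:] + _rand(rng, 13)  # covers stem end + loop
    precursor = "GCAU" + stem + mature[8:] + revcomp_rna("GCAU" + stem)
    window = _rand(rng, 30) + precursor + _rand(rng, 30)
    if window.count(mature) != 1:  # astronomically unlikely at this seed
        pytest.skip("degenerate construction")
    cand = evaluate_candidate(window, SmallRNATag(mature, 5, "t"))
    assert not cand.accepted
    assert not cand.criteria_flags["ii"] or not cand.criteria_flags["iv"]


def test_rejection_reasons_are_exhaustive():
    flags = check_criteria(-10.0, False, False, 3, 9)
    assert set(c for c, ok in flags.items() if not ok) == {"ii", "iii", "iv", "v"}


def _accepted_candidate(mature: str) -> HairpinCandidate:
    arm = "GCAU" + mature + "CGUAGCUAGCAUGCA"
    precursor = arm + "AUCGAUCGAUCG" + revcomp_rna(arm)
    return evaluate_candidate(precursor, SmallRNATag(mature, 1448, "t"))


def test_quantify_exact_mature_only():
    mature = "GCGUAUGAGGAGCCAAGCAUA"
    cand = _accepted_candidate(mature)
    assert cand.accepted
    tags = [SmallRNATag(mature, 1448, "t1")]
    assert quantify_novel(cand, tags) == 1448


def test_quantify_includes_terminal_isoforms_excludes_internal_edits():
    mature = "GCGUAUGAGGAGCCAAGCAUA"
    cand = _accepted_candidate(mature)
    shifted = mature[:-2]  # 2-nt 3' trim
    internal = mature[:10] + ("A" if mature[10] != "A" else "C") + mature[11:]
    tags = [
        SmallRNATag(mature, 100, "t1"),
        SmallRNATag(shifted, 7, "t2"),
        SmallRNATag(internal, 1000, "t3"),
    ]
    assert quantify_novel(cand, tags) == 107


def test_quantify_requires_accepted_candidate():
    cand = _accepted_candidate("GCGUAUGAGGAGCCAAGCAUA")
    cand.criteria_flags["v"] = False
    with pytest.raises(ValueError):
        quantify_novel(cand, [])


def test_all_planted_conforming_hairpins_discovered(study):
    """Default synthetic conditions: every conforming hairpin is found and
    nothing is called where nothing was planted."""
    tags = [
        SmallRNATag(h.mature, 20, f"t{i}")
        for i, h in enumerate(study.hairpin_truth)
        if h.conforming
    ]
    candidates = discover_novel(tags, study.genome)
    assert len(candidates) == len(tags)
    for cand in candidates:
        assert cand.accepted
        assert all(cand.criteria_flags.values())


def test_null_genome_false_positive_rate_bounded():
    """Tags drawn from a pair-poor background-only genome: at most one
    chance hairpin accepted per 100 kb."""
    cfg = SimulationConfig(seed=77, n_hairpins=0)
    genome, _ = simulate_genome_and_hairpins(cfg)
    rng = np.random.default_rng(78)
    seq = genome[0].sequence
    tags = []
    for i in range(25):  # genuine substrings, so they map
        pos = int(rng.integers(0, len(seq) - 21))
        tags.append(SmallRNATag(seq[pos : pos + 21], 5, f"t{i}"))
    candidates = discover_novel(tags, genome)
    assert len(candidates) <= 1


def test_spoiled_hairpins_rejected():
    cfg = SimulationConfig(seed=5, n_hairpins=9, spoiler_fraction=0.34)
    genome, truth = simulate_genome_and_hairpins(cfg)
    spoiled = [h for h in truth if not h.conforming]
    assert spoiled
    tags = [SmallRNATag(h.mature, 5, f"t{i}") for i, h in enumerate(spoiled)]
    assert discover_novel(tags, genome) == []
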