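"""Target prediction: duplex scoring, the six rules, transcriptome scan."""

import numpy as np
import pytest

import oracles
from mirpipe.io import SequenceRecord, revcomp_rna
from mirpipe.simulate import build_violator_site
from mirpipe.targets import (
    TargetDuplex,
    TargetThresholds,
    apply_rules,
    mismatch_score,
    scan_transcriptome,
    score_duplex,
)

MIRNA = "UGGAGAAGCAGGGCACGUGCA"


def _rand(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def _site_with(mirna, changes):
    """Perfect complement with forced states {position(1-based): state}."""
    site = list(revcomp_rna(mirna))
    L = len(mirna)
    for pos, state in changes.items():
        b = mirna[pos - 1]
        idx = L - pos
        if state == "GU":
            assert b in "GU"
            site[idx] = "U" if b == "G" else "G"
        else:
            site[idx] = next(
                x for x in "ACGU"
                if (b, x) not in oracles.WC and (b, x) not in oracles.GU
            )
    return "".join(site)


def test_perfect_complement_scores_zero_and_full_ratio():
    d = score_duplex(MIRNA, revcomp_rna(MIRNA))
    assert d.mismatch_score == 0.0
    assert d.energy_ratio == pytest.approx(100.0)
    assert apply_rules(d) == []


def test_gu_wobble_counts_half():
    d = score_duplex(MIRNA, _site_with(MIRNA, {5: "GU"}))
    assert d.pair_states[4] == "GU"
    assert d.mismatch_score == 0.5


def test_two_mismatches_plus_wobble_score():
    d = score_duplex(MIRNA, _site_with(MIRNA, {15: "mismatch", 18: "mismatch", 5: "GU"}))
    assert d.mismatch_score == 2.5


def test_site_length_mismatch_rejected():
    with pytest.raises(ValueError):
        score_duplex(MIRNA, "ACGU")


def test_mismatch_at_position_ten_fails_seed_rule():
    d = score_duplex(MIRNA, _site_with(MIRNA, {10: "mismatch"}))
    assert "iv" in apply_rules(d)


def test_three_contiguous_mismatches_fail():
    d = score_duplex(MIRNA, _site_with(MIRNA, {18: "mismatch", 19: "mismatch", 20: "mismatch"}))
    assert "ii" in apply_rules(d)


def test_total_score_above_four_fails():
    d = score_duplex(
        MIRNA,
        _site_with(
            MIRNA,
            {13: "mismatch", 15: "mismatch", 17: "mismatch", 19: "mismatch", 2: "GU"},
        ),
    )
    assert d.mismatch_score == 4.5
    assert "i" in apply_rules(d)


def test_energy_ratio_boundary():
    d = score_duplex(MIRNA, revcomp_rna(MIRNA))
    d.energy_ratio = 73.9
    assert "vi" in apply_rules(d)
    d.energy_ratio = 74.0
    assert "vi" not in apply_rules(d)


def test_strict_five_prime_mode_rejects_wobble():
    site = _site_with(MIRNA, {5: "GU"})
    d = score_duplex(MIRNA, site)
    assert "iii" not in apply_rules(d)
    d2 = score_duplex(MIRNA, site)
    assert "iii" in apply_rules(d2, TargetThresholds(strict_five_prime=True))


def test_rules_agree_with_brute_force_checker():
    """10,000 random duplex configurations: implementation matches the
    independently coded rule checker."""
    rng = np.random.default_rng(61)
    th = TargetThresholds()
    for _ in range(10_000):
        L = int(rng.integers(19, 25))
        mirna = _rand(rng, L)
        site = list(revcomp_rna(mirna))
        for _ in range(int(rng.integers(0, 7))):
            site[int(rng.integers(0, L))] = str(rng.choice(list("ACGU")))
        site = "".join(site)
        d = score_duplex(mirna, site)
        got = set(apply_rules(d, th))
        want = oracles.rule_check(list(d.pair_states), d.energy_ratio)
        assert got == want, (mirna, site)


def test_adding_a_mismatch_never_rescues_a_failure():
    rng = np.random.default_rng(67)
    checked = 0
    for _ in range(400):
        mirna = _rand(rng, 21)
        site = list(revcomp_rna(mirna))
        for _ in range(int(rng.integers(0, 5))):
            site[int(rng.integers(0, 21))] = str(rng.choice(list("ACGU")))
        base = score_duplex(mirna, "".join(site))
        if not apply_rules(base):
            continue
        checked += 1
        k = int(rng.integers(0, 21))
        site[k] = next(
            x for x in "ACGU"
            if (mirna[20 - k], x) not in oracles.WC
            and (mirna[20 - k], x) not in oracles.GU
        )
        worse = score_duplex(mirna, "".join(site))
        assert apply_rules(worse), "an extra mismatch turned fail into pass"
    assert checked > 50


def test_scan_recovers_planted_site_coordinates():
    rng = np.random.default_rng(71)
    bg = _rand(rng, 300)
    pos = 137
    site = revcomp_rna(MIRNA)
    seq = bg[:pos] + site + bg[pos + len(site):]
    hits = scan_transcriptome({"m1": MIRNA}, [SequenceRecord("TX1", seq)])
    assert len(hits) == 1
    (h,) = hits
    assert (h.site_start, h.site_end) == (pos + 1, pos + len(MIRNA))
    assert h.site_end - h.site_start + 1 == len(MIRNA)


def test_scan_drops_rule_violating_site():
    rng = np.random.default_rng(73)
    site = build_violator_site(MIRNA, "iv")
    assert site is not None
    bg = _rand(rng, 300)
    seq = bg[:100] + site + bg[100 + len(site):]
    assert scan_transcriptome({"m1": MIRNA}, [SequenceRecord("TX1", seq)]) == []


def test_scan_equals_brute_force_on_null_transcript():
    """Window-by-window re-check of a 10 kb shuffled transcript."""
    rng = np.random.default_rng(79)
    mirna = _rand(rng, 21)
    seq = _rand(rng, 10_000)
    hits = scan_transcriptome({"m": mirna}, [SequenceRecord("TX", seq)])
    brute = 0
    L = len(mirna)
    from mirpipe.folding import duplex_mfe, perfect_complement_mfe

    perfect = perfect_complement_mfe(mirna)
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        states = [
            oracles.pair_state(mirna[p], window[L - 1 - p]) for p in range(L)
        ]
        ratio = 100.0 * duplex_mfe(mirna, window, states) / perfect
        if not oracles.rule_check(states, ratio):
            brute += 1
    assert len(hits) == brute


def test_report_spans_stay_inside_transcript(study_run):
    study, cfg, _ = study_run
    import pandas as pd

    table = pd.read_csv(f"{cfg.outdir}/targets.tsv", sep="\t")
    tx_len = {t.id: len(t.sequence) for t in study.transcripts}
    for row in table.itertuples():
        start, end = (int(x) for x in row.location.split(","))
        assert 1 <= start <= end <= tx_len[row.target_accession]
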