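"""Shared fixtures: printed worked-example sequences and one synthetic
study threaded through the full pipeline (session-scoped, reused by the
pipeline and end-to-end recovery tests)."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirpipe.pipeline import PipelineConfig, run_pipeline
from mirpipe.simulate import SimulationConfig, simulate_study

# Known-miRNA worked examples: family-representative matures with their
# best homolog and printed alignment statistics (matches, mismatches, gaps).
KNOWN_EXAMPLES = {
    "col-miR157a": ("UUGACAGAAGAUAGAGAGCAC", "ath-miR157a", 21, 0, 0, 5531609),
    "col-miR156a": ("UGACAGAAGAGAGUGAGCAC", "ath-miR156a", 20, 0, 0, 1724997),
    "col-miR166a": ("UCGGACCAGGCUUCAUUCCCC", "ath-miR166a", 21, 0, 0, 215636),
    "col-miR167h": ("UGAAGCUGCCAGCAUGAUCUUA", "mdm-miR167h", 22, 0, 0, 154973),
    "col-miR396b-3p": ("GCUCAAGAAAGCUGUGGGAGA", "gma-miR396b-3p", 21, 0, 0, 18695),
    "col-miR168a": ("UCGCUUGGUGCAGGUCGGGAA", "ath-miR168a", 21, 0, 0, 16590),
    "col-miR164a": ("UGGAGAAGCAGGGCACGUGCA", "ath-miR164a", 21, 0, 0, 7491),
    "col-miR169b": ("CAGCCAAGGAUGACUUGCCGG", "ath-miR169b", 21, 0, 0, 2528),
    "col-miR390a": ("AAGCUCAGGAGGGAUAGCGCC", "ath-miR390a", 21, 0, 0, 2952),
    "col-miR160a-3p": ("GCGUAUGAGGAGCCAAGCAUA", "gma-miR160a-3p", 21, 0, 0, 1448),
    "col-miR159a": ("UUUGGAUUGAAGGGAGCUCUA", "ath-miR159a", 21, 0, 0, 484),
    "col-miR171b": ("UGAUUGAGCCGUGCCAAUAUC", "osa-miR171b", 21, 0, 0, 558),
    "col-miR403": ("UUAGAUUCACGCACAAACUCG", "ath-miR403", 21, 0, 0, 282),
    "col-miR398": ("GGAGCGACAUGAGAUCACAUG", "hbr-miR398", 20, 1, 0, 262),
    "col-miR482b": ("UCUUACCUACUCCACCCAUGCC", "ghr-miR482b", 21, 1, 0, 2206),
    "col-miR408": ("AUGCACUGCCUCUUCCCUGGC", "ath-miR408", 21, 0, 0, 129),
    "col-miR397a": ("UCAUUGAGUGCAGCGUUGAUG", "ath-miR397a", 21, 0, 0, 106),
    "col-miR530a": ("UGCAUUUGCACCUGCACCUUU", "csi-miR530a", 20, 1, 0, 81),
    "col-miR393b-3p": ("AUCAUGCGAUCCCUUCGGAAU", "stu-miR393-3p", 20, 1, 0, 61),
    "col-miR394a": ("UUGGCAUUCUGUCCACCUCC", "ath-miR394a", 20, 0, 0, 16),
    "col-miR827a": ("UUAGAUGACCAUCAACAAACA", "ghr-miR827a", 21, 0, 0, 22),
    "col-miR477i": ("ACUCUCCCUCAAGGGCUUCCG", "mes-miR477i", 21, 0, 0, 2),
    "col-miR2111a": ("UAAUCUGCAUCCUGAGGUUUG", "ptc-miR2111a", 21, 0, 0, 15),
    "col-miR172a": ("AGAAUCUUGAUGAUGCUGCAU", "ath-miR172a", 21, 0, 0, 1480),
    "col-miR2950": ("UGGUGUGCAGGGGGUGGAAUA", "ghr-miR2950", 21, 0, 0, 2465),
    "col-miR3954": ("UUGGACAGAGUAAUCACGGUCG", "csi-miR3954", 19, 2, 1, 868222),
    "col-miR158a": ("UCCCAAAUGUAGACAAAGCA", "ath-miR158a", 20, 0, 0, 34),
    "col-miR161.2": ("UCAAUGCAUUGAAAGUGACUA", "ath-miR161.2", 21, 0, 0, 2),
}

# Novel-miRNA worked examples: mature sequence and read count.
NOVEL_EXAMPLES = {
    "col-miRN1-5p": ("GUGGGCGUGCCGGAGUGGUUA", 1448),
    "col-miRN2-3p": ("AGAGGGACUAUGGCCGCUUA", 219),
    "col-miRN3-3p": ("UCGGUUUUGAAUUAGAGACGU", 17),
    "col-miRN4-3p": ("UGAUGAUUGUGAAGAAGAUGA", 14),
    "col-miRN5-3p": ("AGAGGCUCGGUGAAAUAGACAU", 32),
    "col-miRN6-5p": ("UUCGUCCCCGGCAACGGCGCCA", 11),
    "col-miRN7-5p": ("UUUUUUAAUUUUUUAUUUAUC", 7),
    "col-miRN8-5p": ("GUUGAUCAAGUUGUGGAUGGC", 20),
    "col-miRN9-3p": ("AAACUUCGAAUUGGGAGGGC", 2),
    "col-miRN10-3p": ("UGAAUGAUUUCGGACCAGGCU", 3),
    "col-miRN11-3p": ("GUAAGAAGGGGUAGAGAAAAU", 2),
    "col-miRN12-3p": ("AAGAUAGAGAGCACAGAUGAU", 5),
    "col-miRN13-5p": ("GGCGCUGCCUACUCACUCGGACA", 3),
    "col-miRN14-3p": ("GUGAGGCUGGUUUCACAGAGCA", 7),
    "col-miRN15-5p": ("GAGUGCAGCCAAGGAUGACUU", 6),
    "col-miRN16-5p": ("UCAAGGUGGAGAUUGUUAGGA", 4),
    "col-miRN17-5p": ("UUAUACGAUGUGGGAUAUUAC", 6),
}


@pytest.fixture(scope="session")
def printed_matures() -> dict[str, str]:
    out = {name: row[0] for name, row in KNOWN_EXAMPLES.items()}
    out.update({name: row[0] for name, row in NOVEL_EXAMPLES.items()})
    return out


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study: depth 50k, 10 conforming
    hairpins, 20 known matures, 10 compliant target sites."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_run(study, tmp_path_factory):
    """The synthetic study threaded through the full pipeline."""
    base = tmp_path_factory.mktemp("study")
    paths = study.write_all(base / "inputs")
    cfg = PipelineConfig(
        reads=str(paths["reads"]),
        genome=str(paths["genome"]),
        known_db=str(paths["known_db"]),
        ncrna=str(paths["ncrna"]),
        transcripts=str(paths["transcripts"]),
        outdir=str(base / "out"),
    )
    summary = run_pipeline(cfg)
    return study, cfg, summary
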