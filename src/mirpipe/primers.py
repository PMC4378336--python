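"""Stem-loop RT-PCR primer design for miRNA validation assays.

A stem-loop RT primer is a constant hairpin backbone extended at its 3'
end with the exact DNA reverse complement of the last 6 nt of the mature
miRNA — the extension confers the assay's single-miRNA specificity.  The
miRNA-specific forward primer is the DNA transliteration of the miRNA's
first 15 nt with a GC-rich 5' extension grown until the melting
temperature reaches the target; the reverse primer is a universal sequence
taken from the 5' region of the stem-loop backbone.

The default 44-nt backbone is the widely used universal stem-loop scaffold
(44 + 6 = 50 nt total RT primer); the expected end-point amplicon is
``extension + miRNA length + backbone length`` and is checked against the
60-70 bp assay window.

Melting temperatures are nearest-neighbour (SantaLucia unified parameters,
via Biopython) at 250 nM primer in PCR-buffer salt: 50 mM monovalent plus
3 mM Mg2+, expressed as a monovalent equivalent
``Na_eq = Na + 120*sqrt([Mg2+] in mM)`` (~258 mM) with the
``0.368*(N-1)*ln[Na_eq]`` entropy correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .io import revcomp_dna, to_dna

__all__ = [
    "StemLoopBackbone",
    "PrimerSet",
    "DEFAULT_BACKBONE",
    "melting_temp",
    "design_primer_set",
    "primer_report",
]

# Chen-style universal stem-loop scaffold, 44 nt: with the 6-nt
# miRNA-specific extension the RT primer totals 50 nt.
_DEFAULT_BACKBONE_SEQ = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"

# NN melting-temperature conditions (documented constants).
TM_NA_MM = 50.0  # mM monovalent salt
TM_MG_MM = 3.0  # mM Mg2+ (PCR buffer), folded into a Na+ equivalent
TM_NA_EQUIV_MM = TM_NA_MM + 120.0 * math.sqrt(TM_MG_MM)  # ~257.8 mM
TM_PRIMER_NM = 250.0  # nM primer concentration


@dataclass(frozen=True)
class StemLoopBackbone:
    """Constant stem-loop scaffold and its universal-reverse sub-span."""

    sequence: str = _DEFAULT_BACKBONE_SEQ
    reverse_primer_span: tuple[int, int] = (0, 16)  # 5' sub-span, 0-based

    @property
    def universal_reverse(self) -> str:
        lo, hi = self.reverse_primer_span
        return self.sequence[lo:hi]


DEFAULT_BACKBONE = StemLoopBackbone()

AMPLICON_RANGE = (60, 70)


@dataclass(frozen=True)
class PrimerSet:
    mirna_name: str
    stemloop_rt: str
    forward: str
    universal_reverse: str
    forward_tm: float
    expected_amplicon: int


def melting_temp(primer: str) -> float:
    """Nearest-neighbour Tm (degrees C) of a DNA primer.

    SantaLucia unified NN parameters with the 0.368*(N-1)*ln[Na+] entropy
    salt correction at the monovalent-equivalent PCR salt (~258 mM, i.e.
    50 mM monovalent + 3 mM Mg2+), 250 nM primer (excess over template).
    """
    if not primer:
        raise ValueError("empty primer")
    bad = set(primer.upper()) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in primer: {sorted(bad)}")
    return float(
        _mt.Tm_NN(
            primer.upper(),
            nn_table=_mt.DNA_NN3,
            Na=TM_NA_EQUIV_MM,
            dnac1=TM_PRIMER_NM,
            dnac2=0,
            saltcorr=5,
        )
    )


def _gc_extension(core: str, tm_target: float, max_ext: int = 12) -> str:
    """Deterministic alternating-G/C 5' extension until Tm >= target."""
    ext = ""
    while melting_temp(ext + core) < tm_target and len(ext) < max_ext:
        ext += "G" if len(ext) % 2 == 0 else "C"
    return ext


def design_primer_set(
    mirna_name: str,
    mirna: str,
    backbone: StemLoopBackbone = DEFAULT_BACKBONE,
    tm_target: float = 60.0,
) -> PrimerSet:
    """Design the stem-loop RT / forward / universal-reverse primer trio.

    The RT primer is ``backbone + revcomp-DNA(last 6 nt of the miRNA)``;
    the forward primer is a GC extension plus the DNA form of the first
    15 nt.  The expected amplicon is checked against the 60-70 bp window
    (a warning, not an error, when outside).
    """
    mirna_dna = to_dna(mirna)
    if len(mirna_dna) < 18:
        raise ValueError(f"{mirna_name}: miRNA shorter than 18 nt")
    stemloop_rt = backbone.sequence + revcomp_dna(mirna_dna[-6:])
    core = mirna_dna[:15]
    ext = _gc_extension(core, tm_target)
    forward = ext + core
    amplicon = len(ext) + len(mirna_dna) + len(backbone.sequence)
    if not AMPLICON_RANGE[0] <= amplicon <= AMPLICON_RANGE[1]:
        warnings.warn(
            f"{mirna_name}: expected amplicon {amplicon} bp outside "
            f"{AMPLICON_RANGE[0]}-{AMPLICON_RANGE[1]} bp"
        )
    return PrimerSet(
        mirna_name=mirna_name,
        stemloop_rt=stemloop_rt,
        forward=forward,
        universal_reverse=backbone.universal_reverse,
        forward_tm=round(melting_temp(forward), 2),
        expected_amplicon=amplicon,
    )


def primer_report(
    mirnas: Mapping[str, str],
    backbone: StemLoopBackbone = DEFAULT_BACKBONE,
    tm_target: float = 60.0,
) -> pd.DataFrame:
    rows = []
    for name in sorted(mirnas):
        ps = design_primer_set(name, mirnas[name], backbone, tm_target)
        rows.append(
            (
                ps.mirna_name,
                ps.stemloop_rt,
                ps.forward,
                ps.universal_reverse,
                ps.forward_tm,
                ps.expected_amplicon,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "stemloop_rt",
            "forward",
            "universal_reverse",
            "forward_tm",
            "expected_amplicon",
        ],
    )
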