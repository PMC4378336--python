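"""Seeded synthetic inputs with planted ground truth.

The generator emulates the statistical structure of a plant small-RNA
sequencing study: an 18-30 nt tag pool with the mode at 21 nt, a
heavy-tailed (discretised log-normal) count law spanning the 1-to-millions
dynamic range seen in real libraries, contaminant classes at the
fractions a cleaning stage reports, hairpin precursors (conforming and
deliberately spoiled) embedded in a pair-poor background genome, a
miRBase-style known database with planted near-identical matures, and
transcripts carrying rule-compliant and single-rule-violating target
sites.  Every simulated entity traces to a truth record, so recovery can
be asserted exactly.

All randomness flows from ``SimulationConfig.seed``; same config, same
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord, revcomp_rna, to_dna, to_rna

__all__ = [
    "SimulationConfig",
    "HairpinTruth",
    "KnownTruth",
    "SiteTruth",
    "LibraryTruth",
    "SyntheticStudy",
    "simulate_genome_and_hairpins",
    "simulate_known_db",
    "simulate_library",
    "simulate_transcriptome",
    "simulate_study",
]

BASES = np.array(list("ACGU"))

# Length law with the observed shape: mode at 21 nt (42.19%), then 24 and
# 20; 20-24 nt carry 92.69% of the mass.
DEFAULT_LEN_WEIGHTS: dict[int, float] = {
    18: 0.0200, 19: 0.0250, 20: 0.1425, 21: 0.4219, 22: 0.0800,
    23: 0.0530, 24: 0.2295, 25: 0.0120, 26: 0.0060, 27: 0.0040,
    28: 0.0030, 29: 0.0020, 30: 0.0011,
}

# Contaminant fractions of the high-quality total, matching the scale of a
# real cleaning summary (clean reads ~98.9%).
DEFAULT_CONTAMINANT_FRACTIONS: dict[str, float] = {
    "3_adapter_null": 0.0008,
    "insert_null": 0.0001,
    "5_adapter_contaminant": 0.0052,
    "smaller_than_min": 0.0044,
    "poly_a": 0.0001,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    genome_length: int = 100_000
    n_hairpins: int = 10
    spoiler_fraction: float = 0.0
    precursor_len_range: tuple[int, int] = (78, 349)
    mature_len_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEN_WEIGHTS)
    )
    n_known_db: int = 20
    contaminant_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_FRACTIONS)
    )
    read_depth: int = 50_000
    count_lognorm_mu: float = 3.0
    count_lognorm_sigma: float = 1.5
    isomir_fraction: float = 0.10
    n_transcripts: int = 10
    transcript_length: int = 800
    n_planted_targets: int = 10
    # pair-poor background composition (AU-rich keeps spurious stems rare)
    background_weights: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    adapter3: str = "UGGAAUUCUCGGGUGCCAAGG"
    adapter5: str = "GUUCAGAGUUCUACAGUCCGACGAUC"

    def __post_init__(self) -> None:
        if sum(self.contaminant_fractions.values()) > 1:
            raise ValueError("contaminant fractions must sum to <= 1")
        lo, hi = self.precursor_len_range
        if not (60 <= lo <= hi <= 400):
            raise ValueError("precursor range must sit within [60, 400]")


@dataclass
class HairpinTruth:
    name: str
    chrom: str
    start: int  # 0-based, precursor span on genome
    end: int
    mature: str
    mature_start: int  # genome coordinate of the mature
    arm: str
    conforming: bool
    spoiled_criterion: str | None = None


@dataclass
class KnownTruth:
    db_name: str
    family: str
    db_sequence: str
    planted_sequence: str
    edits: int


@dataclass
class SiteTruth:
    mirna_name: str
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    compliant: bool
    spoiled_rule: str | None = None


@dataclass
class LibraryTruth:
    mature_counts: pd.DataFrame  # sequence, count, source, name
    contaminant_counts: dict[str, int]
    clean_reads: int
    total_reads: int


def _rand_seq(rng: np.random.Generator, n: int, weights=None) -> str:
    return "".join(rng.choice(BASES, size=n, p=weights))


def _fuzzy_hit(hay: str, seed: str, max_mismatch: int = 1) -> bool:
    """Does ``seed`` occur in ``hay`` with <= max_mismatch substitutions?
    Mirrors the cleaning stage's tolerant adapter seed search."""
    k = len(seed)
    for i in range(len(hay) - k + 1):
        mm = 0
        for a, b in zip(hay[i : i + k], seed):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def _safe_insert(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> str:
    """A random insert that cannot be misclassified by the cleaning stage."""
    a3 = cfg.adapter3[:8]
    a5 = cfg.adapter5[:8]
    while True:
        s = _rand_seq(rng, n)
        if _fuzzy_hit(s, a3) or _fuzzy_hit(s, a5):
            continue
        if s.count("A") / n >= 0.8:
            continue
        return s


def _sample_len(rng: np.random.Generator, weights: Mapping[int, float]) -> int:
    lengths = sorted(weights)
    p = np.array([weights[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


# ---------------------------------------------------------------------------
# Genome and hairpins


def _build_conforming_hairpin(
    rng: np.random.Generator, cfg: SimulationConfig, arm: str
) -> tuple[str, str, int]:
    """Precursor, mature, mature offset.  Perfect stem: pad + mature + ext
    paired against its full reverse complement around a short loop, so all
    five hairpin criteria hold by construction (pad >= 2 gives room for the
    star's 2-nt 3' overhang)."""
    mature = _safe_insert(rng, _sample_len(rng, cfg.mature_len_weights), cfg)
    pad = _rand_seq(rng, int(rng.integers(4, 7)))
    lo, hi = cfg.precursor_len_range
    max_ext = max(12, (hi - len(pad) * 2 - len(mature) * 2 - 12) // 2)
    ext = _rand_seq(rng, int(rng.integers(12, min(40, max_ext) + 1)))
    loop = _rand_seq(rng, int(rng.integers(10, 21)))
    if arm == "5p":
        five = pad + mature + ext
        precursor = five + loop + revcomp_rna(five)
        offset = len(pad)
    else:
        five = pad + revcomp_rna(mature) + ext
        precursor = five + loop + revcomp_rna(five)
        offset = len(five) + len(loop) + len(ext)
    return precursor, mature, offset


def _build_spoiler(
    rng: np.random.Generator, cfg: SimulationConfig, criterion: str
) -> tuple[str, str, int]:
    """A hairpin deliberately violating one acceptance criterion."""
    mature = _safe_insert(rng, 21, cfg)
    pad = _rand_seq(rng, 4)
    ext = _rand_seq(rng, 12)
    loop = _rand_seq(rng, 14)
    if criterion == "ii":
        # mature straddles the terminal loop
        five = pad + ext + mature[:8]
        precursor = five + mature[8:] + revcomp_rna(five)
        return precursor, mature, len(pad) + len(ext)
    if criterion == "iv":
        # 6-nt bulge opposite the middle of the mature
        five = pad + mature + ext
        three = revcomp_rna(five)
        cut = len(three) - (len(pad) + len(mature) // 2)
        three = three[:cut] + _rand_seq(rng, 6) + three[cut:]
        return five + loop + three, mature, len(pad)
    if criterion == "v":
        # weak sparse stem: every 5th arm position unpaired
        au = np.array(list("AU"))
        mature = "".join(rng.choice(au, size=21))
        while mature.count("A") / 21 >= 0.8 or "AAAAAAAA" in mature:
            mature = "".join(rng.choice(au, size=21))
        five = pad + mature
        three = list(revcomp_rna(five))
        for k in range(2, len(three), 5):
            three[k] = "C" if three[k] != "C" else "G"
        return five + loop + "".join(three), mature, len(pad)
    raise ValueError(f"no spoiler construction for criterion {criterion!r}")


def simulate_genome_and_hairpins(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[HairpinTruth]]:
    """Background genome with embedded precursors plus the truth table."""
    rng = rng or np.random.default_rng(config.seed)
    n_spoil = int(round(config.n_hairpins * config.spoiler_fraction))
    n_ok = config.n_hairpins - n_spoil
    spoiler_cycle = ["ii", "iv", "v"]

    hairpins: list[tuple[str, str, int, str, bool, str | None]] = []
    for k in range(n_ok):
        arm = "5p" if k % 2 == 0 else "3p"
        prec, mature, off = _build_conforming_hairpin(rng, config, arm)
        hairpins.append((prec, mature, off, arm, True, None))
    for k in range(n_spoil):
        crit = spoiler_cycle[k % len(spoiler_cycle)]
        prec, mature, off = _build_spoiler(rng, config, crit)
        hairpins.append((prec, mature, off, "5p", False, crit))

    slot = config.genome_length // (len(hairpins) + 1) if hairpins else 0
    if hairpins and slot < max(len(h[0]) for h in hairpins) + 600:
        raise ValueError("hairpins exceed genome capacity; enlarge genome_length")

    bg = _rand_seq(rng, config.genome_length, np.array(config.background_weights))
    genome = list(bg)
    truth: list[HairpinTruth] = []
    for k, (prec, mature, off, arm, ok, crit) in enumerate(hairpins):
        start = (k + 1) * slot
        genome[start : start + len(prec)] = list(prec)
        truth.append(
            HairpinTruth(
                name=f"hp{k + 1}",
                chrom="chr1",
                start=start,
                end=start + len(prec),
                mature=mature,
                mature_start=start + off,
                arm=arm,
                conforming=ok,
                spoiled_criterion=crit,
            )
        )
    records = [SequenceRecord("chr1", "".join(genome))]
    return records, truth


# ---------------------------------------------------------------------------
# Known database


def simulate_known_db(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[KnownTruth]]:
    """miRBase-style mature database plus planted near-identical matures."""
    rng = rng or np.random.default_rng(config.seed + 1)
    species = ["ath", "osa", "vvi", "gma", "ptc"]
    db: list[SequenceRecord] = []
    truth: list[KnownTruth] = []
    for k in range(config.n_known_db):
        name = f"{species[k % len(species)]}-miR{900 + k}a"
        seq = _safe_insert(rng, int(rng.integers(20, 23)), config)
        db.append(SequenceRecord(name, seq))
        edits = int(rng.integers(0, 4))
        while True:
            planted = list(seq)
            pos = rng.choice(len(seq), size=edits, replace=False)
            for p in pos:
                choices = [b for b in "ACGU" if b != planted[p]]
                planted[p] = choices[int(rng.integers(0, 3))]
            candidate = "".join(planted)
            # edits must not create an adapter-seed look-alike or poly-A run
            if (
                not _fuzzy_hit(candidate, config.adapter3[:8])
                and not _fuzzy_hit(candidate, config.adapter5[:8])
                and candidate.count("A") / len(candidate) < 0.8
            ):
                break
        truth.append(
            KnownTruth(
                db_name=name,
                family=f"miR{900 + k}",
                db_sequence=seq,
                planted_sequence=candidate,
                edits=edits,
            )
        )
    return db, truth


# ---------------------------------------------------------------------------
# Read library


def simulate_library(
    config: SimulationConfig,
    hairpin_truth: Sequence[HairpinTruth],
    known_truth: Sequence[KnownTruth] = (),
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], LibraryTruth]:
    """Adapter-flanked FASTQ-style reads with per-source count truth.

    Counts follow a discretised log-normal (heavy tail); each planted
    mature receives at least one read.  A fraction of each novel mature's
    reads become terminal isomiR variants (1-2 nt trims).  Contaminants are
    drawn binomially at the configured fractions.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    matures: list[tuple[str, str, str]] = []  # (sequence, source, name)
    for h in hairpin_truth:
        if h.conforming:
            matures.append((h.mature, "novel", h.name))
    for k in known_truth:
        matures.append((k.planted_sequence, "known", k.db_name))

    n_cont = {
        cat: int(rng.binomial(config.read_depth, frac))
        for cat, frac in config.contaminant_fractions.items()
    }
    clean_depth = config.read_depth - sum(n_cont.values())

    counts = np.ones(len(matures), dtype=int)
    if matures and clean_depth > len(matures):
        w = np.exp(
            rng.normal(config.count_lognorm_mu, config.count_lognorm_sigma, len(matures))
        )
        extra = rng.multinomial(clean_depth - len(matures), w / w.sum())
        counts = counts + extra

    a3 = config.adapter3
    reads: list[SequenceRecord] = []
    rows = []
    ridx = 0

    def emit(insert: str, n: int) -> None:
        nonlocal ridx
        if n <= 0:
            return
        ridx += 1
        seq = insert + a3
        reads.append(
            SequenceRecord(f"read{ridx}", seq, "I" * len(seq), count=int(n))
        )

    for (seq, source, name), n in zip(matures, counts):
        n = int(n)
        n_iso = int(n * config.isomir_fraction) if source == "novel" else 0
        if n_iso and len(seq) - 2 < 18:
            n_iso = 0  # a trim would drop the variant below the insert window
        emit(seq, n - n_iso)
        if n_iso:
            trim = int(rng.integers(1, 3))
            variant = seq[:-trim] if rng.random() < 0.5 else seq[trim:]
            emit(variant, n_iso)
        rows.append((seq, n, source, name))

    emit_null = n_cont.get("3_adapter_null", 0)
    for _ in range(emit_null):
        ridx += 1
        seq = _safe_insert(rng, 21, config) + _rand_seq(rng, 20)
        while _fuzzy_hit(seq, config.adapter3[:8]):
            seq = _safe_insert(rng, 21, config) + _rand_seq(rng, 20)
        reads.append(SequenceRecord(f"read{ridx}", seq, "I" * len(seq)))
    for _ in range(n_cont.get("insert_null", 0)):
        ridx += 1
        reads.append(SequenceRecord(f"read{ridx}", a3, "I" * len(a3)))
    for _ in range(n_cont.get("5_adapter_contaminant", 0)):
        insert = config.adapter5[:10] + _safe_insert(rng, 12, config)
        emit(insert, 1)
    for _ in range(n_cont.get("smaller_than_min", 0)):
        emit(_safe_insert(rng, int(rng.integers(10, 18)), config), 1)
    for _ in range(n_cont.get("poly_a", 0)):
        emit("A" * 20, 1)

    truth = LibraryTruth(
        mature_counts=pd.DataFrame(
            rows, columns=["sequence", "count", "source", "name"]
        ),
        contaminant_counts=n_cont,
        clean_reads=int(counts.sum()),
        total_reads=int(counts.sum()) + sum(n_cont.values()),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Transcriptome with planted target sites

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _perfect_site(mirna: str) -> str:
    return revcomp_rna(mirna)


def _mutate_site(mirna: str, site: str, pos_1based: int, kind: str) -> str:
    """Force a pair state at a miRNA position of an antiparallel site."""
    L = len(mirna)
    idx = L - pos_1based  # site index facing miRNA position
    b = mirna[pos_1based - 1]
    site = list(site)
    if kind == "mismatch":
        bad = [x for x in "ACGU" if x != _WC[b] and (b, x) not in {("G", "U"), ("U", "G")}]
        site[idx] = bad[0]
    elif kind == "GU":
        if b == "G":
            site[idx] = "U"
        elif b == "U":
            site[idx] = "G"
        else:
            raise ValueError("GU wobble needs G or U on the miRNA side")
    return "".join(site)


def _gu_capable(mirna: str, positions: Sequence[int]) -> list[int]:
    return [p for p in positions if mirna[p - 1] in "GU"]


def build_violator_site(mirna: str, rule: str) -> str | None:
    """A target site violating one scanning rule (None when the miRNA's
    composition cannot realise the violation)."""
    L = len(mirna)
    site = _perfect_site(mirna)
    three_prime = [p for p in range(13, L + 1)]
    if rule == "i":
        for p in three_prime[0:10:2][:5]:
            site = _mutate_site(mirna, site, p, "mismatch")
        return site if len(three_prime[0:10:2][:5]) == 5 else None
    if rule == "ii":
        if L < 16:
            return None
        for p in (14, 15, 16):
            site = _mutate_site(mirna, site, p, "mismatch")
        return site
    if rule == "iii":
        return _mutate_site(mirna, site, 5, "mismatch")
    if rule == "iv":
        capable = _gu_capable(mirna, [10, 11])
        if not capable:
            return None
        return _mutate_site(mirna, site, capable[0], "GU")
    if rule == "v":
        capable = _gu_capable(mirna, [1, 2, 3, 4, 5, 6, 7, 8, 9, 12])
        if len(capable) < 6:
            return None
        for p in capable[:6]:
            site = _mutate_site(mirna, site, p, "GU")
        return site
    if rule == "vi":
        for p in three_prime[0:8:2][:4]:
            site = _mutate_site(mirna, site, p, "mismatch")
        return site
    raise ValueError(f"unknown rule {rule!r}")


def simulate_transcriptome(
    config: SimulationConfig,
    mirnas: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[SiteTruth]]:
    """Background transcripts with planted compliant and violator sites."""
    if not mirnas:
        raise ValueError("miRNA set must be non-empty")
    rng = rng or np.random.default_rng(config.seed + 3)
    names = sorted(mirnas)
    transcripts: list[SequenceRecord] = []
    truth: list[SiteTruth] = []
    tidx = 0

    def plant(mirna_name: str, site: str, compliant: bool, rule: str | None) -> None:
        nonlocal tidx
        tidx += 1
        bg = _rand_seq(
            rng, config.transcript_length, np.array(config.background_weights)
        )
        pos = int(rng.integers(50, config.transcript_length - len(site) - 50))
        seq = bg[:pos] + site + bg[pos + len(site):]
        tid = f"TX{tidx:04d}"
        transcripts.append(SequenceRecord(tid, seq))
        truth.append(
            SiteTruth(
                mirna_name=mirna_name,
                transcript_id=tid,
                start=pos + 1,
                end=pos + len(site),
                compliant=compliant,
                spoiled_rule=rule,
            )
        )

    for k in range(config.n_planted_targets):
        name = names[k % len(names)]
        plant(name, _perfect_site(to_rna(mirnas[name])), True, None)
    for rule in ("i", "ii", "iii", "iv", "v", "vi"):
        for name in names:
            site = build_violator_site(to_rna(mirnas[name]), rule)
            if site is not None:
                plant(name, site, False, rule)
                break
    while len(transcripts) < config.n_transcripts:
        tidx += 1
        transcripts.append(
            SequenceRecord(
                f"TX{tidx:04d}",
                _rand_seq(
                    rng, config.transcript_length, np.array(config.background_weights)
                ),
            )
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genome: list[SequenceRecord]
    hairpin_truth: list[HairpinTruth]
    known_db: list[SequenceRecord]
    known_truth: list[KnownTruth]
    reads: list[SequenceRecord]
    library_truth: LibraryTruth
    transcripts: list[SequenceRecord]
    site_truth: list[SiteTruth]
    ncrna: list[SequenceRecord]

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input file (DNA alphabet on disk) plus truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads": outdir / "reads.fastq",
            "genome": outdir / "genome.fasta",
            "known_db": outdir / "known_mature.fasta",
            "ncrna": outdir / "ncrna.fasta",
            "transcripts": outdir / "transcripts.fasta",
        }
        with open(paths["reads"], "w") as fh:
            for rec in self.reads:
                for rep in range(rec.count):
                    rid = rec.id if rec.count == 1 else f"{rec.id}.{rep + 1}"
                    fh.write(f"@{rid}\n{to_dna(rec.sequence)}\n+\n{rec.quality}\n")
        for key, records in (
            ("genome", self.genome),
            ("known_db", self.known_db),
            ("ncrna", self.ncrna),
            ("transcripts", self.transcripts),
        ):
            with open(paths[key], "w") as fh:
                for rec in records:
                    seq = rec.sequence if key == "known_db" else to_dna(rec.sequence)
                    fh.write(f">{rec.id}\n{seq}\n")
        self.library_truth.mature_counts.to_csv(
            outdir / "truth_matures.tsv", sep="\t", index=False
        )
        pd.DataFrame([vars(h) for h in self.hairpin_truth]).to_csv(
            outdir / "truth_hairpins.tsv", sep="\t", index=False
        )
        pd.DataFrame([vars(s) for s in self.site_truth]).to_csv(
            outdir / "truth_sites.tsv", sep="\t", index=False
        )
        return paths


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate every pipeline input for one synthetic study."""
    config = config or SimulationConfig()
    genome, hairpin_truth = simulate_genome_and_hairpins(config)
    known_db, known_truth = simulate_known_db(config)
    reads, library_truth = simulate_library(config, hairpin_truth, known_truth)
    mirnas = {h.name: h.mature for h in hairpin_truth if h.conforming}
    mirnas.update({k.db_name: k.planted_sequence for k in known_truth[:3]})
    transcripts, site_truth = simulate_transcriptome(config, mirnas)
    rng = np.random.default_rng(config.seed + 4)
    ncrna = [
        SequenceRecord(f"rRNA_{i + 1}", _rand_seq(rng, 120)) for i in range(3)
    ] + [SequenceRecord(f"tRNA_{i + 1}", _rand_seq(rng, 80)) for i in range(3)]
    return SyntheticStudy(
        config=config,
        genome=genome,
        hairpin_truth=hairpin_truth,
        known_db=known_db,
        known_truth=known_truth,
        reads=reads,
        library_truth=library_truth,
        transcripts=transcripts,
        site_truth=site_truth,
        ncrna=ncrna,
    )
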