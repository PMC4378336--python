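"""End-to-end orchestration: cleaning -> ncRNA filter -> known assignment ->
family quantification/conservation -> novel discovery -> target prediction
-> primer design, with every intermediate written to the output directory
and a machine-readable JSON run summary."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cleaning as _cleaning
from . import known as _known
from . import novel as _novel
from . import primers as _primers
from . import targets as _targets
from .cleaning import CleaningParams, clean_library, size_distribution
from .io import read_sequence_file, write_collapsed_fasta, write_tabular
from .novel import NovelThresholds, discover_novel, loci_to_gff3, novel_report
from .targets import TargetThresholds, scan_transcriptome, target_report

log = logging.getLogger("mirpipe")

__all__ = ["PipelineConfig", "run_pipeline", "write_reports"]


@dataclass
class PipelineConfig:
    """Fully serialisable pipeline configuration.

    Every stated analysis constant is a named key: ``mismatch_budget`` (3),
    the novel-stage ``mfe_max`` (-20 kcal/mol), the target-stage
    ``min_energy_ratio`` (74%), ``conservation_min`` (9 species) and the
    18-30 nt insert window of the cleaning stage.
    """

    reads: str = ""
    genome: str = ""
    known_db: str = ""
    ncrna: str = ""
    transcripts: str = ""
    annotation: str = ""
    presence_table: str = ""
    outdir: str = "mirpipe_out"
    seed: int = 1
    mismatch_budget: int = 3
    conservation_min: int = 9
    species_prefix: str = "col"
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    novel: NovelThresholds = field(default_factory=NovelThresholds)
    target: TargetThresholds = field(default_factory=TargetThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("cleaning", CleaningParams),
            ("novel", NovelThresholds),
            ("target", TargetThresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def validate_paths(self) -> None:
        for key in ("reads", "genome", "known_db"):
            value = getattr(self, key)
            if not value or not Path(value).exists():
                raise FileNotFoundError(f"config path {key!r} missing: {value!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns (and writes) the run summary."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: mismatch_budget=%d mfe_max=%s min_energy_ratio=%s "
             "conservation_min=%d insert window=%d-%d nt",
             config.mismatch_budget, config.novel.mfe_max,
             config.target.min_energy_ratio, config.conservation_min,
             config.cleaning.min_len, config.cleaning.max_len)

    summary: dict[str, Any] = {"stages": {}}

    # 1. cleaning
    fmt = "fastq" if config.reads.endswith(("fq", "fastq")) else "fasta"
    raw = read_sequence_file(config.reads, fmt, rna=True)
    tags, report = clean_library(raw, config.cleaning)
    write_tabular(report.to_frame(), outdir / "cleaning_summary.tsv")
    write_tabular(size_distribution(tags), outdir / "size_distribution.tsv")
    write_collapsed_fasta(tags, outdir / "clean_tags.fasta")
    summary["stages"]["cleaning"] = {
        "total_reads": report.total_reads,
        "high_quality": report.high_quality,
        "clean_reads": report.clean_reads,
        "clean_percent": report.clean_percent,
        "unique_tags": len(tags),
    }

    # 2. ncRNA exclusion
    if config.ncrna and Path(config.ncrna).exists():
        exclusion = read_sequence_file(config.ncrna, "fasta", rna=True)
        tags, removed = _known.filter_ncrna(tags, exclusion)
    else:
        removed = {}
    summary["stages"]["ncrna_filter"] = {
        "removed": removed,
        "remaining_tags": len(tags),
    }

    # 3. known assignment + families
    db = read_sequence_file(config.known_db, "fasta", rna=True)
    hits, unassigned = _known.assign_known(
        tags, db, config.mismatch_budget, config.species_prefix
    )
    families = _known.group_and_quantify(hits, tags, config.mismatch_budget)
    if config.presence_table and Path(config.presence_table).exists():
        presence = pd.read_csv(config.presence_table, sep="\t", index_col=0)
    else:
        presence = pd.DataFrame()
    for fam in families:
        _known.classify_conservation(fam, presence, config.conservation_min)
    fam_table = _known.family_report(families)
    write_tabular(fam_table, outdir / "known_families.tsv")
    member_counts = fam_table[["family", "members"]].sort_values(
        ["members", "family"], ascending=[False, True]
    )
    write_tabular(member_counts, outdir / "family_member_counts.tsv")
    summary["stages"]["known"] = {
        "assigned_tags": len(hits),
        "unassigned_tags": len(unassigned),
        "families": len(families),
        "conserved_families": sum(1 for f in families if f.conserved_flag),
    }

    # 4. novel discovery
    genome = read_sequence_file(config.genome, "fasta", rna=True)
    candidates = _novel.discover_novel(
        unassigned, genome, thresholds=config.novel,
        name_prefix=f"{config.species_prefix}-miRN",
    )
    nov_table = novel_report(candidates, tags)
    write_tabular(nov_table, outdir / "novel_mirnas.tsv")
    (outdir / "novel_precursors.gff3").write_text(loci_to_gff3(candidates))
    with open(outdir / "novel_structures.txt", "w") as fh:
        for cand in candidates:
            fh.write(f">{cand.name} mfe={cand.mfe:.2f}\n"
                     f"{cand.precursor}\n{cand.structure.dotbracket}\n")
    summary["stages"]["novel"] = {"accepted": len(candidates)}

    # 5. target prediction
    mirnas: dict[str, str] = {
        fam.representative.assigned_name: fam.representative.tag.sequence
        for fam in families
    }
    mirnas.update({c.name: c.mature for c in candidates})
    if config.transcripts and Path(config.transcripts).exists():
        transcripts = read_sequence_file(config.transcripts, "fasta", rna=True)
        duplexes = scan_transcriptome(mirnas, transcripts, config.target)
        annotation = None
        if config.annotation and Path(config.annotation).exists():
            ann = pd.read_csv(config.annotation, sep="\t")
            annotation = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
        write_tabular(target_report(duplexes, annotation), outdir / "targets.tsv")
        if annotation:
            write_tabular(
                _targets.annotation_summary(duplexes, annotation),
                outdir / "target_annotation_summary.tsv",
            )
        summary["stages"]["targets"] = {
            "passing_sites": len(duplexes),
            "mirnas_with_targets": len({d.mirna_name for d in duplexes}),
        }
    else:
        summary["stages"]["targets"] = {"passing_sites": 0, "skipped": True}

    # 6. primer design
    write_tabular(_primers.primer_report(mirnas), outdir / "primers.tsv")
    summary["stages"]["primers"] = {"designed": len(mirnas)}

    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def write_reports(results: dict[str, Any], outdir: str | Path) -> None:
    """Re-emit the JSON run summary (tables are written stage by stage)."""
    Path(outdir, "run_summary.json").write_text(json.dumps(results, indent=2))
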