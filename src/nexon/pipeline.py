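"""End-to-end orchestration: junctions -> discovery -> quantification -> classification.

Every stated threshold of the analysis is surfaced as a named configuration
parameter with its default: entropy 1.5 bits, discovery percentile 0.10, Psi
denominator floor 40 reads, 50-nt PTC rule, tissue median 0.20, RBP response
0.10 / 0.05 with a strict >10-exon factor floor, and the validation triple
(DeltaPsi >= 0.05, >= 4-fold expression, >= 10 split reads).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import quant
from .annotation import AnnotationCatalog, load_annotation
from .conservation import (
    ConservationTrack,
    infer_phase,
    read_elements_bed,
    read_per_base_bedgraph,
    weighted_element_score,
)
from .discovery import (
    CrypticExonCatalog,
    aggregate_catalog,
    find_cassette_exons,
    learn_thresholds,
    load_assembled_models,
    score_candidate,
    select_cryptic,
    write_catalog_bed12,
    write_catalog_tsv,
)
from .genome import Genome
from .intervals import GenomicInterval
from .junctions import JunctionTable, extract_junctions, filter_junctions
from .nmd import ExonClass, classify_across_transcripts

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    annotation_gtf: str
    genome_fasta: str
    alignments_dir: str  # per-sample <sample>.sam
    models_dir: str  # per-sample <sample>.models.gtf
    elements_bed: str
    design_tsv: str  # sample_id, tissue, condition
    out_dir: str
    per_base_bedgraph: str | None = None

    percentile: float = 0.10
    entropy_min: float = 1.5
    mapq_min: int = 0
    psi_denominator_min: int = 40
    rule_nt: int = 50
    tissue_min_median: float = 0.20
    exon_response_min: float = 0.10
    factor_response_min: float = 0.05
    factor_floor: int = 10
    validation_dpsi_min: float = 0.05
    validation_fold_min: float = 4.0
    validation_reads_min: int = 10
    control_condition: str = "control"
    nmd_condition: str = "CHX"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class PipelineResult:
    catalog: CrypticExonCatalog
    classifications: list[ExonClass]
    junctions: JunctionTable
    psi_by_condition: dict[GenomicInterval, dict[str, float | None]]
    delta_nmd: dict[GenomicInterval, float | None]
    stage_counts: dict[str, int] = field(default_factory=dict)
    out_dir: Path | None = None


def _read_design(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    stage("load_annotation")
    genome = Genome(config.genome_fasta)
    catalog = load_annotation(config.annotation_gtf, genome)
    counts["genes"] = len(catalog.genes)

    stage("junctions")
    design = _read_design(config.design_tsv)
    if not design:
        raise RuntimeError("stage junctions: empty design table")
    samples = [row["sample_id"] for row in design]
    sample_tissues = {row["sample_id"]: row["tissue"] for row in design}
    sample_conditions = {row["sample_id"]: row["condition"] for row in design}
    junctions = JunctionTable(entropy_threshold=config.entropy_min)
    for sample in samples:
        sam = Path(config.alignments_dir) / f"{sample}.sam"
        if not sam.exists():
            raise RuntimeError(f"stage junctions: missing alignment file {sam}")
        records = extract_junctions(sam, sample, mapq_min=config.mapq_min)
        table = filter_junctions(records, genome, entropy_min=config.entropy_min)
        for rec in table.records():
            junctions.add(rec)
        junctions.summary.retained += table.summary.retained
        junctions.summary.dropped_entropy += table.summary.dropped_entropy
        junctions.summary.dropped_noncanonical += table.summary.dropped_noncanonical
    counts["junctions_retained"] = junctions.summary.retained
    counts["junctions_dropped_entropy"] = junctions.summary.dropped_entropy
    counts["junctions_dropped_noncanonical"] = junctions.summary.dropped_noncanonical

    stage("discovery")
    track = ConservationTrack(read_elements_bed(config.elements_bed))
    per_sample_selected = []
    n_candidates = 0
    for sample in samples:
        models_path = Path(config.models_dir) / f"{sample}.models.gtf"
        if not models_path.exists():
            raise RuntimeError(f"stage discovery: missing models file {models_path}")
        models = load_assembled_models(models_path)
        cands = find_cassette_exons(models, catalog, sample)
        n_candidates += len(cands)
        scored = [(c, score_candidate(c, track, junctions)) for c in cands]
        annotated_metrics = [
            m for c, m in scored if c.annotated and m.coverage > 0
        ]
        thresholds = learn_thresholds(
            annotated_metrics, sample, percentile=config.percentile
        )
        per_sample_selected.append(select_cryptic(scored, thresholds, catalog))
    counts["cassette_candidates"] = n_candidates
    counts["selected_per_sample"] = sum(len(s) for s in per_sample_selected)

    cryptic = aggregate_catalog(per_sample_selected, junctions, sample_tissues)
    counts["catalog_exons"] = len(cryptic)
    write_catalog_tsv(cryptic, out_dir / "catalog.tsv")
    write_catalog_bed12(cryptic, out_dir / "catalog.bed")

    stage("classification")
    intron_to_gene: dict[tuple[str, int, int], str] = {}
    for gene in catalog.genes:
        for tx in gene.transcripts:
            for intron in tx.introns():
                intron_to_gene.setdefault(intron.key(), gene.gene_id)
    classifications = []
    for entry in cryptic.entries:
        gene_id = intron_to_gene.get(entry.skip_intron.key())
        if gene_id is None:
            log.warning("no host gene for catalog exon %s", entry.exon)
            continue
        classifications.append(
            classify_across_transcripts(
                entry.exon, catalog.genes_by_id[gene_id], genome, rule_nt=config.rule_nt
            )
        )
    _write_classifications(classifications, out_dir / "classifications.tsv")

    stage("quantification")
    grouping_condition = {s: sample_conditions[s] for s in samples}
    psi_by_condition: dict[GenomicInterval, dict[str, float | None]] = {}
    delta_nmd: dict[GenomicInterval, float | None] = {}
    for entry in cryptic.entries:
        values = quant.compute_psi(
            junctions, entry, grouping_condition,
            denominator_min=config.psi_denominator_min,
        )
        by_group = {v.group: v for v in values}
        psi_by_condition[entry.exon] = {g: v.psi for g, v in by_group.items()}
        if config.nmd_condition in by_group and config.control_condition in by_group:
            delta_nmd[entry.exon] = quant.delta_psi(
                by_group[config.nmd_condition], by_group[config.control_condition]
            ).delta
    _write_psi(psi_by_condition, delta_nmd, out_dir / "psi_by_condition.tsv")

    psi_matrix = quant.per_sample_psi_matrix(
        junctions, cryptic.entries, samples,
        denominator_min=config.psi_denominator_min,
    )
    tissue_specific = quant.tissue_specific_exons(
        psi_matrix, sample_tissues, min_median=config.tissue_min_median
    )
    counts["tissue_specific_exons"] = len(tissue_specific)

    stage("conservation")
    phase_rows = []
    per_base = (
        read_per_base_bedgraph(config.per_base_bedgraph)
        if config.per_base_bedgraph
        else None
    )
    full_track = ConservationTrack(track.elements, per_base) if per_base else track
    for entry in cryptic.entries:
        score = weighted_element_score(entry.exon, full_track)
        phase = ""
        if per_base:
            try:
                phase = infer_phase(entry.exon, full_track).phase
            except ValueError:
                phase = ""
        phase_rows.append((entry.exon, score, phase))
    with open(out_dir / "conservation.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tweighted_score\tinferred_phase\n")
        for exon, score, phase in phase_rows:
            fh.write(
                f"{exon.chrom}\t{exon.start}\t{exon.end}\t{exon.strand}\t"
                f"{score:.2f}\t{phase}\n"
            )

    stage("report")
    _write_report(counts, classifications, out_dir / "report.txt")
    with open(out_dir / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)

    return PipelineResult(
        catalog=cryptic,
        classifications=classifications,
        junctions=junctions,
        psi_by_condition=psi_by_condition,
        delta_nmd=delta_nmd,
        stage_counts=counts,
        out_dir=out_dir,
    )


def class_proportions(classifications: list[ExonClass]) -> dict[str, float]:
    """Fractions of poison / coding / non-coding exons by representative verdict.

    Non-coding pools UTR placements and incompatible insertions, mirroring
    the three-way accounting against the representative transcript.
    """
    n = len(classifications)
    if n == 0:
        return {"poison": 0.0, "coding": 0.0, "non_coding": 0.0}
    poison = sum(
        1 for c in classifications
        if c.mane_verdict and c.mane_verdict.verdict == "poison"
    )
    coding = sum(
        1 for c in classifications
        if c.mane_verdict and c.mane_verdict.verdict == "coding"
    )
    return {
        "poison": poison / n,
        "coding": coding / n,
        "non_coding": (n - poison - coding) / n,
    }


def group_counts(classifications: list[ExonClass]) -> dict[str, int]:
    out = {"APE": 0, "APC": 0, "MIX": 0, "undefined": 0}
    for c in classifications:
        out[c.group or "undefined"] += 1
    return out


def _write_classifications(classifications: list[ExonClass], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tmane_verdict\tgroup\tframeshift\t"
            "ptc_distance\tper_transcript\n"
        )
        for c in classifications:
            mane = c.mane_verdict.verdict if c.mane_verdict else ""
            dist = (
                c.mane_verdict.ptc_distance
                if c.mane_verdict and c.mane_verdict.ptc_distance is not None
                else ""
            )
            per_tx = ";".join(
                f"{tid}:{v.verdict}" for tid, v in sorted(c.per_transcript.items())
            )
            fh.write(
                f"{c.exon.chrom}\t{c.exon.start}\t{c.exon.end}\t{c.exon.strand}\t"
                f"{mane}\t{c.group or 'NA'}\t{int(c.frameshift)}\t{dist}\t{per_tx}\n"
            )


def _write_psi(psi_by_condition, delta_nmd, path: Path) -> None:
    conditions = sorted({g for d in psi_by_condition.values() for g in d})
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\t"
            + "\t".join(f"psi_{c}" for c in conditions)
            + "\tdelta_nmd\n"
        )
        for exon in sorted(psi_by_condition):
            row = [exon.chrom, str(exon.start), str(exon.end), exon.strand]
            for c in conditions:
                v = psi_by_condition[exon].get(c)
                row.append("" if v is None else f"{v:.4f}")
            d = delta_nmd.get(exon)
            row.append("" if d is None else f"{d:.4f}")
            fh.write("\t".join(row) + "\n")


def _write_report(counts, classifications, path: Path) -> None:
    props = class_proportions(classifications)
    groups = group_counts(classifications)
    with open(path, "w") as fh:
        fh.write("cryptic exon discovery report\n")
        fh.write("=============================\n\n")
        for key in sorted(counts):
            fh.write(f"{key}: {counts[key]}\n")
        fh.write("\nclass proportions (vs representative transcript):\n")
        for key in ("poison", "coding", "non_coding"):
            fh.write(f"  {key}: {props[key]:.3f}\n")
        fh.write("\ntranscript-set groups:\n")
        for key in ("APE", "APC", "MIX", "undefined"):
            fh.write(f"  {key}: {groups[key]}\n")
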