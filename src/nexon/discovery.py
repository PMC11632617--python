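"""Cassette-exon discovery from per-sample assembled transcript models.

An internal exon [x, y) of an assembled model is a cassette candidate when
its flanking introns [a, x) and [y, b) bracket an annotated skip intron
[a, b).  Each candidate is scored with three metrics — element conservation,
mean read coverage, and split-read support (the minimum over the two
inclusion junctions) — and kept only when all three exceed per-sample
thresholds learned as the 10th percentile of the same metrics over annotated
cassette exons.  Surviving candidates are aggregated across samples and
purged of anything overlapping an annotated exon, yielding the cryptic-exon
catalog.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .annotation import AnnotationCatalog, TranscriptModel
from .conservation import ConservationTrack, weighted_element_score
from .intervals import GenomicInterval
from .junctions import JunctionTable

log = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 0.10


@dataclass
class CassetteCandidate:
    exon: GenomicInterval
    upstream_intron: GenomicInterval  # [a, x)
    downstream_intron: GenomicInterval  # [y, b)
    sample_id: str
    annotated: bool
    transcript_id: str = ""
    coverage_attr: float | None = None  # assembler-reported exon coverage

    def __post_init__(self) -> None:
        a, x = self.upstream_intron.start, self.upstream_intron.end
        y, b = self.downstream_intron.start, self.downstream_intron.end
        if not (a < x < y < b):
            raise ValueError(
                f"invalid cassette geometry a={a} x={x} y={y} b={b}"
            )

    @property
    def skip_intron(self) -> GenomicInterval:
        return GenomicInterval(
            self.exon.chrom,
            self.upstream_intron.start,
            self.downstream_intron.end,
            self.exon.strand,
        )


@dataclass
class MetricVector:
    conservation: float  # element-score units, 0-1000 scale
    coverage: float  # mean reads per nt
    split_support: int  # min over the two inclusion junctions

    def __post_init__(self) -> None:
        if self.conservation < 0 or self.coverage < 0 or self.split_support < 0:
            raise ValueError("metrics must be non-negative")


@dataclass
class ThresholdSet:
    conservation_min: float
    coverage_min: float
    split_min: float
    percentile: float
    sample_id: str


@dataclass
class CatalogEntry:
    exon: GenomicInterval
    upstream_intron: GenomicInterval
    downstream_intron: GenomicInterval
    supporting_samples: list[str]
    supporting_tissues: list[str]
    pooled_support: int

    @property
    def skip_intron(self) -> GenomicInterval:
        return GenomicInterval(
            self.exon.chrom,
            self.upstream_intron.start,
            self.downstream_intron.end,
            self.exon.strand,
        )


@dataclass
class CrypticExonCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def exons(self) -> list[GenomicInterval]:
        return [e.exon for e in self.entries]


def load_assembled_models(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse an assembler-emitted GTF (StringTie-like, optional cov attribute).

    Per-exon coverage is read from the exon ``cov`` attribute when present
    and stored in the transcript's ``attributes["cov"]`` list (one value per
    exon, genomic order).
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons_by_tx = defaultdict(list)
    for f in db.features_of_type("exon"):
        exons_by_tx[f.attributes["transcript_id"][0]].append(f)
    models = []
    for tid, feats in exons_by_tx.items():
        feats.sort(key=lambda f: f.start)
        strand = feats[0].strand
        if strand not in ("+", "-"):
            log.warning("skipping strand-ambiguous assembled transcript %s", tid)
            continue
        exons = [
            GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in feats
        ]
        covs = [
            float(f.attributes["cov"][0]) if "cov" in f.attributes else None
            for f in feats
        ]
        gene_id = feats[0].attributes.get("gene_id", [tid])[0]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=feats[0].seqid,
                strand=strand,
                exons=exons,
                attributes={"cov": covs},
            )
        )
    return models


def find_cassette_exons(
    models: list[TranscriptModel],
    catalog: AnnotationCatalog,
    sample_id: str,
) -> list[CassetteCandidate]:
    """Internal exons whose skip intron [a, b) is annotated.

    Models with fewer than three exons contribute nothing.  ``annotated`` is
    set iff the exon matches an annotated exon exactly (same coordinates and
    strand).
    """
    candidates = []
    for model in models:
        if len(model.exons) < 3:
            continue
        covs = model.attributes.get("cov", [None] * len(model.exons))
        for i in range(1, len(model.exons) - 1):
            prev_exon, exon, next_exon = model.exons[i - 1 : i + 2]
            skip = (model.chrom, prev_exon.end, next_exon.start)
            if skip not in catalog.annotated_introns:
                continue
            candidates.append(
                CassetteCandidate(
                    exon=exon,
                    upstream_intron=GenomicInterval(
                        model.chrom, prev_exon.end, exon.start, model.strand
                    ),
                    downstream_intron=GenomicInterval(
                        model.chrom, exon.end, next_exon.start, model.strand
                    ),
                    sample_id=sample_id,
                    annotated=catalog.is_annotated_exon(exon),
                    transcript_id=model.transcript_id,
                    coverage_attr=covs[i],
                )
            )
    return candidates


def score_candidate(
    cand: CassetteCandidate,
    track: ConservationTrack,
    junctions: JunctionTable,
    coverage_track: dict[str, dict[int, float]] | None = None,
    conservation_denominator: str = "intersection",
) -> MetricVector:
    """Three discovery metrics for one candidate in its own sample.

    Coverage prefers the assembler-reported per-exon value and falls back to
    the mean of the per-base ``coverage_track`` (chrom -> position -> depth)
    over the exon; having neither is an error naming the exon.
    """
    conservation = weighted_element_score(
        cand.exon, track, denominator=conservation_denominator
    )
    if cand.coverage_attr is not None:
        coverage = cand.coverage_attr
    else:
        per_chrom = (coverage_track or {}).get(cand.exon.chrom, {})
        values = [
            per_chrom[pos]
            for pos in range(cand.exon.start, cand.exon.end)
            if pos in per_chrom
        ]
        if not values:
            raise ValueError(f"no coverage source for exon {cand.exon}")
        coverage = sum(values) / len(values)
    support = min(
        junctions.count(cand.sample_id, cand.upstream_intron),
        junctions.count(cand.sample_id, cand.downstream_intron),
    )
    return MetricVector(
        conservation=conservation, coverage=coverage, split_support=support
    )


def nearest_rank_quantile(values: list[float], fraction: float) -> float:
    """Nearest-rank lower quantile: the k-th smallest with k = ceil(q * n)."""
    if not values:
        raise ValueError("quantile of an empty list")
    ordered = sorted(values)
    k = max(1, math.ceil(fraction * len(ordered)))
    return ordered[k - 1]


def learn_thresholds(
    annotated_metrics: list[MetricVector],
    sample_id: str,
    percentile: float = DEFAULT_PERCENTILE,
    min_exons: int = 10,
) -> ThresholdSet:
    """Per-sample thresholds from the annotated-cassette metric distributions."""
    if len(annotated_metrics) < min_exons:
        raise ValueError(
            f"sample {sample_id}: only {len(annotated_metrics)} annotated cassette "
            f"exons scored; at least {min_exons} required to learn thresholds"
        )
    return ThresholdSet(
        conservation_min=nearest_rank_quantile(
            [m.conservation for m in annotated_metrics], percentile
        ),
        coverage_min=nearest_rank_quantile(
            [m.coverage for m in annotated_metrics], percentile
        ),
        split_min=nearest_rank_quantile(
            [float(m.split_support) for m in annotated_metrics], percentile
        ),
        percentile=percentile,
        sample_id=sample_id,
    )


def select_cryptic(
    scored: list[tuple[CassetteCandidate, MetricVector]],
    thresholds: ThresholdSet,
    catalog: AnnotationCatalog,
    stranded_overlap: bool = True,
) -> list[tuple[CassetteCandidate, MetricVector]]:
    """Keep unannotated candidates passing all three thresholds and the overlap filter."""
    kept = []
    for cand, metrics in scored:
        if cand.annotated:
            continue
        if metrics.conservation < thresholds.conservation_min:
            continue
        if metrics.coverage < thresholds.coverage_min:
            continue
        if metrics.split_support < thresholds.split_min:
            continue
        if catalog.overlapping_exons(cand.exon, stranded=stranded_overlap):
            continue
        kept.append((cand, metrics))
    return kept


def aggregate_catalog(
    per_sample: list[list[tuple[CassetteCandidate, MetricVector]]],
    junctions: JunctionTable,
    sample_tissues: dict[str, str],
) -> CrypticExonCatalog:
    """Deduplicate selected candidates across samples into one catalog.

    An exon seen with several flanking-intron pairs keeps the pair with the
    highest pooled split-read support (pooled minimum over the two junctions,
    summed across all samples); ties go to the shorter skip intron, then the
    leftmost upstream boundary.
    """
    by_exon: dict[tuple, dict[tuple, list[CassetteCandidate]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for sample_list in per_sample:
        for cand, _ in sample_list:
            exon_key = (
                cand.exon.chrom, cand.exon.start, cand.exon.end, cand.exon.strand
            )
            pair_key = (cand.upstream_intron.start, cand.downstream_intron.end)
            by_exon[exon_key][pair_key].append(cand)

    entries = []
    for exon_key, pairs in sorted(by_exon.items()):
        chrom, start, end, strand = exon_key
        exon = GenomicInterval(chrom, start, end, strand)

        def pooled_support(pair_key: tuple[int, int]) -> int:
            a, b = pair_key
            up = GenomicInterval(chrom, a, start, strand)
            down = GenomicInterval(chrom, end, b, strand)
            return min(junctions.pooled_count(up), junctions.pooled_count(down))

        best = min(
            pairs,
            key=lambda pk: (-pooled_support(pk), pk[1] - pk[0], pk[0]),
        )
        a, b = best
        samples = sorted({c.sample_id for cands in pairs.values() for c in cands})
        tissues = sorted(
            {sample_tissues.get(s, s) for s in samples}
        )
        entries.append(
            CatalogEntry(
                exon=exon,
                upstream_intron=GenomicInterval(chrom, a, start, strand),
                downstream_intron=GenomicInterval(chrom, end, b, strand),
                supporting_samples=samples,
                supporting_tissues=tissues,
                pooled_support=pooled_support(best),
            )
        )
    return CrypticExonCatalog(entries=entries)


def write_catalog_tsv(catalog: CrypticExonCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tflank_a\tflank_b\t"
            "pooled_support\tsamples\ttissues\n"
        )
        for e in catalog.entries:
            fh.write(
                f"{e.exon.chrom}\t{e.exon.start}\t{e.exon.end}\t{e.exon.strand}\t"
                f"{e.upstream_intron.start}\t{e.downstream_intron.end}\t"
                f"{e.pooled_support}\t{','.join(e.supporting_samples)}\t"
                f"{','.join(e.supporting_tissues)}\n"
            )


def write_catalog_bed12(catalog: CrypticExonCatalog, path: str | Path) -> None:
    """BED12: the cassette unit from skip-intron start to end, exon as the block."""
    with open(path, "w") as fh:
        for i, e in enumerate(catalog.entries):
            chrom_start = e.upstream_intron.start
            chrom_end = e.downstream_intron.end
            block_start = e.exon.start - chrom_start
            fh.write(
                f"{e.exon.chrom}\t{chrom_start}\t{chrom_end}\tcryptic_{i}\t"
                f"{min(1000, e.pooled_support)}\t{e.exon.strand}\t"
                f"{chrom_start}\t{chrom_end}\t0,0,0\t1\t"
                f"{e.exon.length},\t{block_start},\n"
            )
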