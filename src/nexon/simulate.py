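"""Self-contained synthetic cohorts with a planted ground truth.

The generator emulates the inputs of the discovery pipeline at toy scale:

* a genome with multi-exon protein-coding genes (valid ORFs, GT/AG introns,
  both strands) and, per gene, one annotated skip isoform that makes one
  internal exon a bona-fide annotated cassette exon;
* cryptic cassette exons planted strictly inside introns with engineered
  splice sites, of known class — *poison* plants carry an in-frame stop
  whose 3' end lies >= 50 nt upstream of the final junction of the modified
  mRNA, *coding* plants are frame-preserving and stop-free, *utr* plants sit
  in a 5'-UTR intron — plus low-conservation *decoy* exons that exercise the
  discovery filters' specificity;
* element and per-base conservation tracks in which protein-coding sequence
  shows the codon-periodic third-position dip and poison-exon sequence does
  not;
* per-sample spliced alignments (SAM), assembled transcript models (GTF with
  per-exon ``cov``) and coverage tracks, with junction counts drawn
  binomially from each event's true inclusion level; an NMD-inhibition
  condition ("CHX") multiplies the inclusion odds of poison plants.

Every planted exon is self-verified at generation time by running the
package's own insertion/translation classifier; a plant whose verdict does
not match its intended class is a generator bug and raises.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationCatalog, GeneModel, TranscriptModel, write_gtf
from .conservation import ConservationTrack, ScoredElement
from .genome import Genome, reverse_complement
from .intervals import GenomicInterval
from .junctions import JunctionRecord, JunctionTable
from .nmd import classify_ptc, insert_exon

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the reference toy cohort: 20 genes carrying 15 planted
    cryptic exons (11 poison / 3 coding / 1 UTR, i.e. the ~73/20/7% class
    split) and 5 low-conservation decoys, sequencing depth 100 junction reads
    per cassette event, and an NMD-inhibition condition that triples the
    inclusion odds of poison exons.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_len_range: tuple[int, int] = (90, 150)
    intron_len_range: tuple[int, int] = (300, 600)
    utr_len_range: tuple[int, int] = (40, 80)
    min_cds_len: int = 150

    n_poison: int = 11
    n_coding: int = 3
    n_utr: int = 1
    n_decoys: int = 5
    plant_len_range: tuple[int, int] = (75, 130)

    tissues: tuple[str, ...] = ("brain", "liver")
    plant_psi_range: tuple[float, float] = (0.25, 0.75)
    cassette_psi_range: tuple[float, float] = (0.05, 0.95)
    decoy_psi_range: tuple[float, float] = (0.2, 0.6)
    chx_multiplier: float = 3.0

    annotated_score_mean: float = 520.0
    annotated_score_sd: float = 100.0
    planted_score_range: tuple[float, float] = (500.0, 900.0)
    decoy_score_range: tuple[float, float] = (5.0, 80.0)
    background_element_prob: float = 0.5
    background_score_range: tuple[float, float] = (5.0, 60.0)

    phylo_base: float = 3.0
    phylo_contrast: float = 1.5
    phylo_noise_sd: float = 0.5
    phylo_utr_base: float = 0.5

    read_len: int = 150
    retention_rate: float = 0.05

    def plant_classes(self) -> list[str]:
        classes = (
            ["poison"] * self.n_poison
            + ["coding"] * self.n_coding
            + ["utr"] * self.n_utr
            + ["decoy"] * self.n_decoys
        )
        if len(classes) > self.n_genes:
            raise ValueError("more planted events than genes (one event per gene)")
        return classes


@dataclass
class SampleDesign:
    sample_id: str
    tissue: str
    condition: str = "control"


@dataclass
class CohortDesign:
    samples: list[SampleDesign]
    depth: int = 100
    overdispersion: float | None = None  # beta-binomial concentration, None = binomial

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.samples:
            raise ValueError("design needs at least one sample")


def default_cohort_design(depth: int = 100) -> CohortDesign:
    samples = []
    i = 0
    for condition in ("control", "CHX"):
        for tissue in ("brain", "liver"):
            for _ in range(2):
                i += 1
                samples.append(SampleDesign(f"s{i}", tissue, condition))
    return CohortDesign(samples=samples, depth=depth)


@dataclass
class PlantedExon:
    exon: GenomicInterval
    gene_id: str
    exon_class: str  # poison / coding / utr / decoy
    phase: int | None  # conservation-profile phase for coding plants
    psi: dict[str, float]  # per-tissue true inclusion
    condition_multipliers: dict[str, float] = field(default_factory=dict)


@dataclass
class AnnotatedCassette:
    exon: GenomicInterval
    gene_id: str
    psi: dict[str, float]


@dataclass
class CassetteEvent:
    """One inclusion/skip unit to simulate reads for."""

    exon: GenomicInterval
    upstream_intron: GenomicInterval
    downstream_intron: GenomicInterval
    psi: dict[str, float]
    condition_multipliers: dict[str, float]
    kind: str  # annotated / poison / coding / utr / decoy
    gene_id: str

    @property
    def skip_intron(self) -> GenomicInterval:
        return GenomicInterval(
            self.exon.chrom,
            self.upstream_intron.start,
            self.downstream_intron.end,
            self.exon.strand,
        )


@dataclass
class SyntheticTruth:
    seed: int
    planted: list[PlantedExon]
    cassettes: list[AnnotatedCassette]
    events: list[CassetteEvent]

    def planted_by_class(self, exon_class: str) -> list[PlantedExon]:
        return [p for p in self.planted if p.exon_class == exon_class]

    @property
    def true_cryptic(self) -> list[PlantedExon]:
        """Planted exons that discovery is expected to report (not decoys)."""
        return [p for p in self.planted if p.exon_class != "decoy"]


@dataclass
class LocusSet:
    genome_path: Path
    gtf_path: Path
    truth_path: Path
    genome: Genome
    catalog: AnnotationCatalog
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# locus construction


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=int(n)))


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=int(n))
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _plant_sequence(
    rng: np.random.Generator, length: int, f0: int, exon_class: str
) -> str:
    """Exon sequence safe for its intended class in insertion frame ``f0``.

    ``f0`` is the codon index of the exon's first base.  Partial boundary
    codons are C-padded (no stop codon contains C), interior codons are drawn
    stop-free; poison exons then get one interior codon replaced by TGA.
    """
    lead = (3 - f0) % 3
    interior = (length - lead) // 3
    tail = length - lead - interior * 3
    if interior < 5:
        raise ValueError("planted exon too short for safe construction")
    codons = list(_rand_codons(rng, interior)[i : i + 3] for i in range(0, interior * 3, 3))
    if exon_class == "poison":
        codons[2] = "TGA"
    return "C" * lead + "".join(codons) + "C" * tail


@dataclass
class _GeneDraft:
    gene_id: str
    strand: str
    exon_locals: list[tuple[int, int]]
    cds_local: tuple[int, int]
    cassette_index: int
    locus: list[str]
    plant_local: tuple[int, int] | None
    plant_intron: int | None
    plant_class: str | None
    plant_phase: int | None


def _build_gene(
    rng: np.random.Generator, gene_id: str, config: SimulationConfig,
    plant_class: str | None,
) -> _GeneDraft:
    utr_gene = plant_class == "utr"
    lo, hi = config.exons_per_gene
    n_ex = int(rng.integers(max(lo, 4), hi + 1))
    exon_lens = [int(rng.integers(*config.exon_len_range)) for _ in range(n_ex)]
    intron_lens = [int(rng.integers(*config.intron_len_range)) for _ in range(n_ex - 1)]

    if utr_gene:
        # first exon entirely untranslated; CDS starts inside exon 2
        utr5 = exon_lens[0] + int(rng.integers(10, 40))
    else:
        utr5 = int(rng.integers(*config.utr_len_range))
        utr5 = min(utr5, exon_lens[0] - 10)
    utr3 = int(rng.integers(*config.utr_len_range))
    utr3 = min(utr3, exon_lens[-1] - 10)
    total = sum(exon_lens)
    cds_len = total - utr5 - utr3
    cds_len -= cds_len % 3
    while cds_len < config.min_cds_len:
        exon_lens[1] += 60
        total += 60
        cds_len = total - utr5 - utr3
        cds_len -= cds_len % 3
    utr3 = total - utr5 - cds_len

    mrna = (
        _rand_seq(rng, utr5)
        + "ATG"
        + _rand_codons(rng, cds_len // 3 - 2)
        + "TAA"
        + _rand_seq(rng, utr3)
    )

    # lay out the locus in transcribed orientation
    locus: list[str] = []
    exon_locals: list[tuple[int, int]] = []
    cursor = 0
    mrna_cursor = 0
    for j, elen in enumerate(exon_lens):
        exon_locals.append((cursor, cursor + elen))
        locus.append(mrna[mrna_cursor : mrna_cursor + elen])
        mrna_cursor += elen
        cursor += elen
        if j < n_ex - 1:
            ilen = intron_lens[j]
            locus.append("GT" + _rand_seq(rng, ilen - 4) + "AG")
            cursor += ilen
    seq = list("".join(locus))

    prefix = np.cumsum([0] + exon_lens)

    def local_of_mrna(i: int) -> int:
        j = int(np.searchsorted(prefix, i, side="right")) - 1
        return exon_locals[j][0] + (i - prefix[j])

    cds_local = (local_of_mrna(utr5), local_of_mrna(utr5 + cds_len - 1) + 1)

    plant_local = plant_intron = plant_phase = None
    if plant_class is not None:
        plen = int(rng.integers(*config.plant_len_range))
        if plant_class == "coding":
            plen -= plen % 3
        if utr_gene:
            intron_i = 0
        else:
            intron_i = int(rng.integers(0, n_ex - 2))
            # keep the annotated cassette exon away from the host intron so
            # the plant's skip junction is not also a cassette flank junction
            if not [k for k in range(1, n_ex - 1) if k not in (intron_i, intron_i + 1)]:
                intron_i = 0
        a_loc = exon_locals[intron_i][1]
        b_loc = exon_locals[intron_i + 1][0]
        off = int(rng.integers(30, (b_loc - a_loc) - plen - 30))
        x_loc = a_loc + off
        y_loc = x_loc + plen
        ins_mrna = int(prefix[intron_i + 1])
        f0 = (ins_mrna - utr5) % 3
        if plant_class in ("poison", "coding"):
            exon_seq = _plant_sequence(rng, plen, f0, plant_class)
            plant_phase = (plen - f0) % 3 if plant_class == "coding" else None
        else:
            exon_seq = _rand_seq(rng, plen)
        seq[x_loc - 2 : x_loc] = "AG"
        seq[x_loc:y_loc] = exon_seq
        seq[y_loc : y_loc + 2] = "GT"
        plant_local = (x_loc, y_loc)
        plant_intron = intron_i

    if plant_intron is None:
        cassette_index = int(rng.integers(1, n_ex - 1))
    else:
        choices = [
            k for k in range(1, n_ex - 1) if k not in (plant_intron, plant_intron + 1)
        ]
        cassette_index = int(choices[rng.integers(0, len(choices))])

    strand = "+" if rng.random() < 0.5 else "-"
    draft = _GeneDraft(
        gene_id=gene_id,
        strand=strand,
        exon_locals=exon_locals,
        cds_local=cds_local,
        cassette_index=cassette_index,
        locus=seq,
        plant_local=plant_local,
        plant_intron=plant_intron,
        plant_class=plant_class,
        plant_phase=plant_phase,
    )
    if strand == "-":
        _flip_draft(draft)
    return draft


def _flip_draft(draft: _GeneDraft) -> None:
    n = len(draft.locus)
    draft.locus = list(reverse_complement("".join(draft.locus)))
    flip = lambda iv: (n - iv[1], n - iv[0])
    n_ex = len(draft.exon_locals)
    draft.exon_locals = sorted(flip(e) for e in draft.exon_locals)
    draft.cds_local = flip(draft.cds_local)
    draft.cassette_index = n_ex - 1 - draft.cassette_index
    if draft.plant_local is not None:
        draft.plant_local = flip(draft.plant_local)


def generate_locus_set(
    config: SimulationConfig, out_dir: str | Path, seed: int
) -> LocusSet:
    """Generate genome FASTA, annotation GTF and ground truth.

    Deterministic under ``seed``: running twice yields byte-identical files.
    Each planted exon is verified against the package's own PTC classifier.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    classes: list[str | None] = list(config.plant_classes())
    classes += [None] * (config.n_genes - len(classes))
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_cursor = {"chr1": 0, "chr2": 0}
    spacer = 300

    genes: list[GeneModel] = []
    planted: list[PlantedExon] = []
    cassettes: list[AnnotatedCassette] = []
    events: list[CassetteEvent] = []

    for g, plant_class in enumerate(classes):
        gene_id = f"G{g + 1:03d}"
        draft = _build_gene(rng, gene_id, config, plant_class)
        chrom = "chr1" if g % 2 == 0 else "chr2"
        pad = _rand_seq(rng, spacer)
        chrom_seqs[chrom].append(pad)
        offset = chrom_cursor[chrom] + spacer
        chrom_seqs[chrom].append("".join(draft.locus))
        chrom_cursor[chrom] = offset + len(draft.locus)

        exons = [
            GenomicInterval(chrom, offset + s, offset + e, draft.strand)
            for s, e in draft.exon_locals
        ]
        cds = (offset + draft.cds_local[0], offset + draft.cds_local[1])
        rep = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            chrom=chrom,
            strand=draft.strand,
            exons=exons,
            cds_start=cds[0],
            cds_end=cds[1],
        )
        k = draft.cassette_index
        skip_tx = TranscriptModel(
            transcript_id=f"{gene_id}.t2",
            gene_id=gene_id,
            chrom=chrom,
            strand=draft.strand,
            exons=exons[:k] + exons[k + 1 :],
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcripts=[rep, skip_tx],
                representative_id=rep.transcript_id,
            )
        )

        cassette_psi = {
            t: float(rng.uniform(*config.cassette_psi_range)) for t in config.tissues
        }
        cassettes.append(
            AnnotatedCassette(exon=exons[k], gene_id=gene_id, psi=cassette_psi)
        )
        events.append(
            CassetteEvent(
                exon=exons[k],
                upstream_intron=GenomicInterval(
                    chrom, exons[k - 1].end, exons[k].start, draft.strand
                ),
                downstream_intron=GenomicInterval(
                    chrom, exons[k].end, exons[k + 1].start, draft.strand
                ),
                psi=cassette_psi,
                condition_multipliers={},
                kind="annotated",
                gene_id=gene_id,
            )
        )

        if plant_class is not None:
            plant_iv = GenomicInterval(
                chrom,
                offset + draft.plant_local[0],
                offset + draft.plant_local[1],
                draft.strand,
            )
            psi_range = (
                config.decoy_psi_range
                if plant_class == "decoy"
                else config.plant_psi_range
            )
            psi = {t: float(rng.uniform(*psi_range)) for t in config.tissues}
            multipliers = (
                {"CHX": config.chx_multiplier} if plant_class == "poison" else {}
            )
            planted.append(
                PlantedExon(
                    exon=plant_iv,
                    gene_id=gene_id,
                    exon_class=plant_class,
                    phase=draft.plant_phase,
                    psi=psi,
                    condition_multipliers=multipliers,
                )
            )
            # host intron boundaries on the representative transcript
            host = next(
                iv for iv in rep.introns()
                if iv.start < plant_iv.start and plant_iv.end < iv.end
            )
            events.append(
                CassetteEvent(
                    exon=plant_iv,
                    upstream_intron=GenomicInterval(
                        chrom, host.start, plant_iv.start, draft.strand
                    ),
                    downstream_intron=GenomicInterval(
                        chrom, plant_iv.end, host.end, draft.strand
                    ),
                    psi=psi,
                    condition_multipliers=multipliers,
                    kind=plant_class,
                    gene_id=gene_id,
                )
            )

    # trailing padding, write FASTA
    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in ("chr1", "chr2"):
            chrom_seqs[chrom].append(_rand_seq(rng, spacer))
            seq = "".join(chrom_seqs[chrom])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    stale = Path(str(genome_path) + ".fai")
    if stale.exists():
        stale.unlink()

    catalog = AnnotationCatalog(genes)
    gtf_path = out_dir / "annotation.gtf"
    write_gtf(catalog, gtf_path)

    genome = Genome(genome_path)
    truth = SyntheticTruth(
        seed=seed, planted=planted, cassettes=cassettes, events=events
    )
    _self_verify(truth, catalog, genome)

    truth_path = out_dir / "truth.tsv"
    write_truth_tsv(truth, truth_path, config.tissues)
    return LocusSet(
        genome_path=genome_path,
        gtf_path=gtf_path,
        truth_path=truth_path,
        genome=genome,
        catalog=catalog,
        truth=truth,
        config=config,
    )


_EXPECTED_VERDICT = {"poison": "poison", "coding": "coding", "utr": "utr_5prime"}


def _self_verify(
    truth: SyntheticTruth, catalog: AnnotationCatalog, genome: Genome
) -> None:
    for plant in truth.planted:
        if plant.exon_class == "decoy":
            continue
        rep = catalog.genes_by_id[plant.gene_id].representative
        result = insert_exon(rep, plant.exon, genome)
        if result.status != "inserted":
            raise RuntimeError(
                f"generator bug: plant {plant.exon} incompatible with {rep.transcript_id}"
            )
        verdict = classify_ptc(result)
        if verdict.verdict != _EXPECTED_VERDICT[plant.exon_class]:
            raise RuntimeError(
                f"generator bug: plant {plant.exon} class {plant.exon_class} "
                f"classified {verdict.verdict}"
            )


def write_truth_tsv(
    truth: SyntheticTruth, path: str | Path, tissues: tuple[str, ...]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["kind", "chrom", "start", "end", "strand", "gene_id", "phase"]
            + [f"psi_{t}" for t in tissues]
            + ["chx_multiplier"]
        )
        for p in truth.planted:
            writer.writerow(
                [
                    p.exon_class, p.exon.chrom, p.exon.start, p.exon.end,
                    p.exon.strand, p.gene_id,
                    "" if p.phase is None else p.phase,
                ]
                + [f"{p.psi[t]:.4f}" for t in tissues]
                + [p.condition_multipliers.get("CHX", 1.0)]
            )
        for c in truth.cassettes:
            writer.writerow(
                ["annotated", c.exon.chrom, c.exon.start, c.exon.end,
                 c.exon.strand, c.gene_id, ""]
                + [f"{c.psi[t]:.4f}" for t in tissues]
                + [1.0]
            )


# ---------------------------------------------------------------------------
# conservation tracks


def periodic_profile(
    rng: np.random.Generator,
    length: int,
    phase: int,
    base: float,
    contrast: float,
    noise_sd: float,
) -> list[float]:
    """Per-base scores with the third-codon-position dip under ``phase``."""
    noise = rng.normal(0.0, noise_sd, size=length)
    return [
        base - contrast * ((i - phase) % 3 == 2) + float(noise[i])
        for i in range(length)
    ]


def generate_conservation(
    locus: LocusSet, out_dir: str | Path, seed: int
) -> tuple[Path, Path, ConservationTrack]:
    """Element BED and per-base bedGraph tracks matching the planted truth.

    Annotated exons and non-decoy plants are covered by high-score elements;
    decoys and intron background score low.  The per-base track covers exon
    positions only: coding sequence (annotated CDS and coding plants) gets
    the codon-periodic dip, poison/utr plants are flat-high, UTR sequence is
    flat-low.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = locus.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    elements: list[ScoredElement] = []
    per_base: dict[str, dict[int, float]] = {}

    def set_scores(iv: GenomicInterval, values: list[float]) -> None:
        """Assign values walking the interval in transcription order."""
        chrom_map = per_base.setdefault(iv.chrom, {})
        positions = list(range(iv.start, iv.end))
        if iv.strand == "-":
            positions = positions[::-1]
        for pos, val in zip(positions, values):
            chrom_map[pos] = val

    for gene in locus.catalog.genes:
        rep = gene.representative
        for exon in rep.exons:
            score = float(
                np.clip(
                    rng.normal(cfg.annotated_score_mean, cfg.annotated_score_sd),
                    100.0, 1000.0,
                )
            )
            elements.append(
                ScoredElement(GenomicInterval(exon.chrom, exon.start, exon.end), score)
            )
        # per-base: periodic over CDS, flat-low over UTRs
        mrna_pos = 0
        utr5_len = _utr5_length(rep)
        cds_len = _cds_mrna_length(rep)
        for exon in rep.exons_transcribed():
            values = []
            for i in range(exon.length):
                m = mrna_pos + i
                if utr5_len <= m < utr5_len + cds_len:
                    codon_index = (m - utr5_len) % 3
                    values.append(
                        cfg.phylo_base
                        - cfg.phylo_contrast * (codon_index == 2)
                        + float(rng.normal(0.0, cfg.phylo_noise_sd))
                    )
                else:
                    values.append(
                        cfg.phylo_utr_base + float(rng.normal(0.0, cfg.phylo_noise_sd))
                    )
            set_scores(exon, values)
            mrna_pos += exon.length
        for intron in rep.introns():
            if rng.random() < cfg.background_element_prob and intron.length > 80:
                s = intron.start + int(rng.integers(10, intron.length - 60))
                elements.append(
                    ScoredElement(
                        GenomicInterval(intron.chrom, s, s + 50),
                        float(rng.uniform(*cfg.background_score_range)),
                    )
                )

    for plant in locus.truth.planted:
        if plant.exon_class == "decoy":
            score = float(rng.uniform(*cfg.decoy_score_range))
        else:
            score = float(rng.uniform(*cfg.planted_score_range))
        elements.append(
            ScoredElement(
                GenomicInterval(plant.exon.chrom, plant.exon.start, plant.exon.end),
                score,
            )
        )
        if plant.exon_class == "coding":
            values = periodic_profile(
                rng, plant.exon.length, plant.phase,
                cfg.phylo_base, cfg.phylo_contrast, cfg.phylo_noise_sd,
            )
        elif plant.exon_class == "decoy":
            values = [
                cfg.phylo_utr_base + float(v)
                for v in rng.normal(0.0, cfg.phylo_noise_sd, size=plant.exon.length)
            ]
        else:  # poison / utr plants: no periodicity
            values = [
                cfg.phylo_base + float(v)
                for v in rng.normal(0.0, cfg.phylo_noise_sd, size=plant.exon.length)
            ]
        set_scores(plant.exon, values)

    elements.sort(key=lambda el: (el.interval.chrom, el.interval.start))
    elements_path = out_dir / "elements.bed"
    with open(elements_path, "w") as fh:
        for i, el in enumerate(elements):
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\t"
                f"el_{i}\t{el.score:.1f}\n"
            )
    per_base_path = out_dir / "phylo.bedgraph"
    with open(per_base_path, "w") as fh:
        for chrom in sorted(per_base):
            for pos in sorted(per_base[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{per_base[chrom][pos]:.4f}\n")

    return elements_path, per_base_path, ConservationTrack(elements, per_base)


def _utr5_length(tx: TranscriptModel) -> int:
    ordered = tx.exons_transcribed()
    cum = 0
    for exon in ordered:
        if tx.strand == "+":
            if exon.start <= tx.cds_start < exon.end:
                return cum + (tx.cds_start - exon.start)
        else:
            if exon.start < tx.cds_end <= exon.end:
                return cum + (exon.end - tx.cds_end)
        cum += exon.length
    raise ValueError(f"CDS start not exonic in {tx.transcript_id}")


def _cds_mrna_length(tx: TranscriptModel) -> int:
    total = 0
    for exon in tx.exons:
        total += max(0, min(exon.end, tx.cds_end) - max(exon.start, tx.cds_start))
    return total


# ---------------------------------------------------------------------------
# read / count simulation


def _effective_psi(event: CassetteEvent, sample: SampleDesign) -> float:
    psi = event.psi[sample.tissue]
    mult = event.condition_multipliers.get(sample.condition, 1.0)
    if mult == 1.0 or psi in (0.0, 1.0):
        return psi
    odds = psi / (1.0 - psi) * mult
    return odds / (1.0 + odds)


def _draw_inclusion(
    rng: np.random.Generator, depth: int, psi: float, overdispersion: float | None
) -> int:
    if psi <= 0.0:
        return 0
    if psi >= 1.0:
        return depth
    if overdispersion:
        p = rng.beta(psi * overdispersion, (1.0 - psi) * overdispersion)
    else:
        p = psi
    return int(rng.binomial(depth, p))


def _sample_rng(seed: int, sample_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 303, sample_index, stream]))


def simulate_junction_table(
    locus: LocusSet, design: CohortDesign, seed: int
) -> tuple[JunctionTable, dict[tuple[str, int], tuple[int, int]]]:
    """Draw junction counts directly into a filtered-format JunctionTable.

    Fast path bypassing SAM emission: every event contributes its two
    inclusion junctions (count = sampled inclusion reads each) and its skip
    junction, with reads spread over four offsets so the records would pass
    the entropy filter.  Returns the table plus a map from
    (sample_id, event index) to (inclusion, skip) counts.
    """
    table = JunctionTable()
    counts: dict[tuple[str, int], tuple[int, int]] = {}
    offsets = (30, 55, 80, 105)
    for si, sample in enumerate(design.samples):
        rng = _sample_rng(seed, si, 1)
        for ei, event in enumerate(locus.truth.events):
            psi = _effective_psi(event, sample)
            n_inc = _draw_inclusion(rng, design.depth, psi, design.overdispersion)
            n_skip = design.depth - n_inc
            counts[(sample.sample_id, ei)] = (n_inc, n_skip)
            for junction, n in (
                (event.upstream_intron, n_inc),
                (event.downstream_intron, n_inc),
                (event.skip_intron, n_skip),
            ):
                if n == 0:
                    continue
                rec = JunctionRecord(junction, sample.sample_id)
                for j, off in enumerate(offsets):
                    c = n // len(offsets) + (1 if j < n % len(offsets) else 0)
                    if c:
                        rec.add(off, c)
                table.add(rec)
    return table, counts


def simulate_sample(
    locus: LocusSet,
    sample: SampleDesign,
    sample_index: int,
    design: CohortDesign,
    out_dir: str | Path,
    seed: int,
    emit_constitutive: bool = True,
) -> dict[str, Path]:
    """Emit SAM alignments, an assembled-model GTF and a coverage bedGraph.

    Junction reads are single-end ``read_len`` nt with the splice encoded as
    an N CIGAR operation and the junction offset drawn uniformly; cassette
    events are sampled as in :func:`simulate_junction_table` (the same seed
    stream, so files and fast path agree).  Constitutive junctions not used
    by any event receive full-depth reads; flanking introns of planted exons
    additionally receive retention reads (contiguous alignments crossing the
    exon-intron boundary).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = locus.config
    rng = _sample_rng(seed, sample_index, 1)
    rng_reads = _sample_rng(seed, sample_index, 2)

    sam_path = out_dir / f"{sample.sample_id}.sam"
    gtf_path = out_dir / f"{sample.sample_id}.models.gtf"
    cov_path = out_dir / f"{sample.sample_id}.coverage.bedgraph"

    read_len = cfg.read_len
    lines: list[str] = []
    read_no = 0

    def emit_junction_reads(junction: GenomicInterval, n: int) -> None:
        nonlocal read_no
        if n <= 0:
            return
        offs = rng_reads.integers(20, read_len - 20, size=n)
        for o in offs:
            o = int(o)
            pos0 = junction.start - o
            cigar = f"{o}M{junction.length}N{read_len - o}M"
            seq = locus.genome.fetch(
                junction.chrom, pos0, junction.start
            ) + locus.genome.fetch(
                junction.chrom, junction.end, junction.end + read_len - o
            )
            read_no += 1
            lines.append(
                f"r{sample.sample_id}_{read_no}\t0\t{junction.chrom}\t{pos0 + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{'I' * read_len}\n"
            )

    def emit_retention_reads(intron: GenomicInterval, n: int) -> None:
        nonlocal read_no
        half = read_len // 2
        for _ in range(n):
            pos0 = intron.start - half
            seq = locus.genome.fetch(intron.chrom, pos0, pos0 + read_len)
            read_no += 1
            lines.append(
                f"r{sample.sample_id}_{read_no}\t0\t{intron.chrom}\t{pos0 + 1}\t60\t"
                f"{read_len}M\t*\t0\t0\t{seq}\t{'I' * read_len}\n"
            )

    event_counts: dict[int, tuple[int, int]] = {}
    used_junctions: set[tuple[str, int, int]] = set()
    for ei, event in enumerate(locus.truth.events):
        psi = _effective_psi(event, sample)
        n_inc = _draw_inclusion(rng, design.depth, psi, design.overdispersion)
        event_counts[ei] = (n_inc, design.depth - n_inc)
        used_junctions.update(
            iv.key()
            for iv in (event.upstream_intron, event.downstream_intron, event.skip_intron)
        )

    for ei, event in enumerate(locus.truth.events):
        n_inc, n_skip = event_counts[ei]
        emit_junction_reads(event.upstream_intron, n_inc)
        emit_junction_reads(event.downstream_intron, n_inc)
        emit_junction_reads(event.skip_intron, n_skip)
        if event.kind != "annotated" and cfg.retention_rate > 0:
            n_ret = int(rng_reads.binomial(design.depth, cfg.retention_rate))
            emit_retention_reads(event.upstream_intron, n_ret)

    if emit_constitutive:
        for gene in locus.catalog.genes:
            for intron in gene.representative.introns():
                if intron.key() not in used_junctions:
                    emit_junction_reads(intron, design.depth)

    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in locus.genome.chromosomes:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{locus.genome.chrom_length(chrom)}\n")
        fh.writelines(lines)

    _write_models_gtf(locus, sample, design, event_counts, gtf_path, cov_path)
    return {"sam": sam_path, "models": gtf_path, "coverage": cov_path}


def _write_models_gtf(
    locus: LocusSet,
    sample: SampleDesign,
    design: CohortDesign,
    event_counts: dict[int, tuple[int, int]],
    gtf_path: Path,
    cov_path: Path,
) -> None:
    cfg = locus.config
    events_by_gene: dict[str, list[tuple[int, CassetteEvent]]] = {}
    for ei, event in enumerate(locus.truth.events):
        events_by_gene.setdefault(event.gene_id, []).append((ei, event))

    cov_lines: list[str] = []
    with open(gtf_path, "w") as fh:

        def write_model(tid: str, gene_id: str, exons, covs) -> None:
            chrom = exons[0].chrom
            strand = exons[0].strand
            attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
            fh.write(
                f"{chrom}\tsim\ttranscript\t{exons[0].start + 1}\t{exons[-1].end}\t"
                f".\t{strand}\t.\t{attrs}\n"
            )
            for exon, cov in zip(exons, covs):
                fh.write(
                    f"{chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t{strand}\t.\t"
                    f'{attrs} cov "{cov:.2f}";\n'
                )
                cov_lines.append(f"{chrom}\t{exon.start}\t{exon.end}\t{cov:.2f}\n")

        for gene in locus.catalog.genes:
            rep = gene.representative
            base_cov = design.depth * cfg.read_len
            ref_covs = []
            gene_events = events_by_gene.get(gene.gene_id, [])
            cassette = {
                e.exon.key(): event_counts[ei][0]
                for ei, e in gene_events
                if e.kind == "annotated"
            }
            for exon in rep.exons:
                n_inc = cassette.get(exon.key())
                cov = (
                    n_inc * cfg.read_len / exon.length
                    if n_inc is not None
                    else base_cov / exon.length
                )
                ref_covs.append(cov)
            write_model(f"{gene.gene_id}.{sample.sample_id}.ref", gene.gene_id,
                        rep.exons, ref_covs)

            for ei, event in gene_events:
                if event.kind == "annotated":
                    continue
                n_inc, _ = event_counts[ei]
                if n_inc == 0:
                    continue
                exons = sorted(rep.exons + [event.exon], key=lambda e: e.start)
                covs = [
                    n_inc * cfg.read_len / e.length
                    if e.key() == event.exon.key()
                    else base_cov / e.length
                    for e in exons
                ]
                write_model(
                    f"{gene.gene_id}.{sample.sample_id}.alt{ei}", gene.gene_id,
                    exons, covs,
                )

    with open(cov_path, "w") as fh:
        fh.writelines(sorted(set(cov_lines)))


def generate_cohort(
    config: SimulationConfig,
    design: CohortDesign,
    out_dir: str | Path,
    seed: int,
) -> tuple[LocusSet, dict[str, dict[str, Path]]]:
    """Full dataset: locus set, conservation tracks, per-sample files, design TSV."""
    out_dir = Path(out_dir)
    locus = generate_locus_set(config, out_dir, seed)
    generate_conservation(locus, out_dir, seed)
    sample_files = {}
    samples_dir = out_dir / "samples"
    for si, sample in enumerate(design.samples):
        sample_files[sample.sample_id] = simulate_sample(
            locus, sample, si, design, samples_dir, seed
        )
    with open(out_dir / "design.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "tissue", "condition", "depth"])
        for s in design.samples:
            writer.writerow([s.sample_id, s.tissue, s.condition, design.depth])
    return locus, sample_files
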