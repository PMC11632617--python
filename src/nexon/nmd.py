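"""Poison / protein-coding classification of cassette exons via the 50-nt rule.

A cassette exon is *poison* when its inclusion introduces a premature
termination codon (PTC) that triggers nonsense-mediated decay.  The operative
criterion is the 50-nt rule: a stop codon is recognised as a PTC when it lies
at least 50 nt upstream of the last exon-exon junction of the mRNA, because
the exon junction complex deposited near that junction is not displaced by
the terminating ribosome.

The procedure: splice the candidate exon into a host transcript, rebuild the
mRNA from genomic sequence, translate from the annotated start codon, find
the first in-frame stop, and measure its distance to the last junction.
Distances are measured from the stop codon's 3' end, and "at least 50" is
inclusive (>= 50 nt -> PTC).  The annotated stop codon itself is never a PTC:
only stops strictly upstream of it are candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import GeneModel, TranscriptModel
from .genome import Genome
from .intervals import GenomicInterval

DEFAULT_RULE_NT = 50

STOP_CODONS = {"TAA", "TAG", "TGA"}

VERDICTS = ("poison", "coding", "utr_5prime", "utr_3prime", "incompatible")


@dataclass
class InsertionResult:
    """Outcome of splicing a cassette exon into a transcript model."""

    transcript_id: str
    status: str  # "inserted" or "incompatible"
    modified_exons: list[GenomicInterval] = field(default_factory=list)
    mrna: str = ""
    cds_start_mrna: int | None = None
    cds_end_mrna: int | None = None  # one past the annotated stop codon
    last_junction_mrna: int | None = None
    exon_mrna_span: tuple[int, int] | None = None


@dataclass
class PtcVerdict:
    verdict: str
    ptc_distance: int | None = None
    nonstop: bool = False


@dataclass
class ExonClass:
    """Aggregate classification of one exon across a gene's transcripts."""

    exon: GenomicInterval
    per_transcript: dict[str, PtcVerdict]
    mane_verdict: PtcVerdict | None
    group: str | None  # APE / APC / MIX, None when no coding context exists
    frameshift: bool


def _mrna_position(exons: list[GenomicInterval], strand: str, genomic_pos: int) -> int:
    """mRNA coordinate of the base at ``genomic_pos`` (transcription order)."""
    ordered = exons if strand == "+" else list(reversed(exons))
    cum = 0
    for exon in ordered:
        if exon.start <= genomic_pos < exon.end:
            within = (
                genomic_pos - exon.start if strand == "+" else exon.end - 1 - genomic_pos
            )
            return cum + within
        cum += exon.length
    raise ValueError(f"genomic position {genomic_pos} not exonic")


def insert_exon(
    transcript: TranscriptModel,
    exon: GenomicInterval,
    genome: Genome,
) -> InsertionResult:
    """Splice ``exon`` into ``transcript`` and rebuild the mRNA.

    The insertion succeeds only when the exon lies strictly within one intron
    of the transcript; exons overlapping a transcript exon, outside the
    transcript span, or on another chromosome/strand come back with status
    ``incompatible`` (not an exception).
    """
    if exon.chrom != transcript.chrom or exon.strand != transcript.strand:
        return InsertionResult(transcript.transcript_id, "incompatible")
    inside = any(
        intron.start < exon.start and exon.end < intron.end
        for intron in transcript.introns()
    )
    if not inside:
        return InsertionResult(transcript.transcript_id, "incompatible")

    modified = sorted(transcript.exons + [exon], key=lambda e: e.start)
    strand = transcript.strand
    ordered = modified if strand == "+" else list(reversed(modified))
    mrna = "".join(genome.fetch_transcribed(e) for e in ordered)
    last_junction = len(mrna) - ordered[-1].length
    e0 = _mrna_position(modified, strand, exon.start if strand == "+" else exon.end - 1)
    span = (e0, e0 + exon.length)

    cds_start_mrna = cds_end_mrna = None
    if transcript.is_coding:
        if strand == "+":
            cds_start_mrna = _mrna_position(modified, strand, transcript.cds_start)
            cds_end_mrna = _mrna_position(modified, strand, transcript.cds_end - 1) + 1
        else:
            cds_start_mrna = _mrna_position(modified, strand, transcript.cds_end - 1)
            cds_end_mrna = _mrna_position(modified, strand, transcript.cds_start) + 1

    return InsertionResult(
        transcript_id=transcript.transcript_id,
        status="inserted",
        modified_exons=modified,
        mrna=mrna,
        cds_start_mrna=cds_start_mrna,
        cds_end_mrna=cds_end_mrna,
        last_junction_mrna=last_junction,
        exon_mrna_span=span,
    )


def classify_ptc(result: InsertionResult, rule_nt: int = DEFAULT_RULE_NT) -> PtcVerdict:
    """Apply the 50-nt rule to an insertion.

    Returns ``poison`` when the first in-frame stop lies upstream of the
    annotated stop and its 3' end sits >= ``rule_nt`` nt before the last
    exon-exon junction; ``coding`` when translation terminates normally, when
    a premature stop fails the distance rule, or when a frameshift reads
    through the annotated stop; ``utr_5prime``/``utr_3prime`` when the
    insertion point is untranslated (including whole non-coding transcripts,
    reported as ``utr_5prime``).
    """
    if result.status != "inserted":
        raise ValueError("classify_ptc requires a successful insertion")
    if result.cds_start_mrna is None:
        return PtcVerdict("utr_5prime")
    e0, e1 = result.exon_mrna_span
    if e1 <= result.cds_start_mrna:
        return PtcVerdict("utr_5prime")
    if e0 >= result.cds_end_mrna:
        return PtcVerdict("utr_3prime")

    mrna = result.mrna
    for s in range(result.cds_start_mrna, len(mrna) - 2, 3):
        codon = mrna[s : s + 3]
        if codon in STOP_CODONS:
            stop_end = s + 3
            if stop_end >= result.cds_end_mrna:
                # annotated stop, or a read-through stop downstream of it
                return PtcVerdict("coding")
            distance = result.last_junction_mrna - stop_end
            if distance >= rule_nt:
                return PtcVerdict("poison", ptc_distance=distance)
            return PtcVerdict("coding", ptc_distance=distance)
    return PtcVerdict("coding", nonstop=True)


def is_frameshift(exon_length: int) -> bool:
    """True iff inclusion shifts the reading frame (length not a multiple of 3)."""
    if exon_length < 1:
        raise ValueError(f"exon length must be positive, got {exon_length}")
    return exon_length % 3 != 0


def classify_across_transcripts(
    exon: GenomicInterval,
    gene: GeneModel,
    genome: Genome,
    rule_nt: int = DEFAULT_RULE_NT,
) -> ExonClass:
    """Insert the exon into every transcript of the gene and aggregate.

    The APE/APC/MIX group is taken over transcripts where insertion succeeded
    in a coding context (verdict poison or coding): APE when all are poison,
    APC when none is, MIX otherwise.  UTR verdicts are recorded per transcript
    but excluded from the dichotomy; when no transcript offers a coding
    context the group is None.
    """
    per_transcript: dict[str, PtcVerdict] = {}
    mane_verdict = None
    for tx in gene.transcripts:
        result = insert_exon(tx, exon, genome)
        if result.status != "inserted":
            verdict = PtcVerdict("incompatible")
        else:
            verdict = classify_ptc(result, rule_nt=rule_nt)
        per_transcript[tx.transcript_id] = verdict
        if tx.transcript_id == gene.representative_id:
            mane_verdict = verdict

    coding_context = [
        v.verdict for v in per_transcript.values() if v.verdict in ("poison", "coding")
    ]
    if not coding_context:
        group = None
    elif all(v == "poison" for v in coding_context):
        group = "APE"
    elif all(v == "coding" for v in coding_context):
        group = "APC"
    else:
        group = "MIX"

    return ExonClass(
        exon=exon,
        per_transcript=per_transcript,
        mane_verdict=mane_verdict,
        group=group,
        frameshift=is_frameshift(exon.length),
    )
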