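"""Evolutionary conservation scoring and codon-periodicity phase inference.

Two kinds of conservation evidence are used.  Element-level scores
(phastCons-element style, 0-1000) give each candidate exon a single weighted
score used by the discovery filter.  Per-base scores (phyloP style) resolve
codon periodicity: protein-coding sequence is least constrained at the third
codon position, so averaging per-base scores at each of the three positions
under each of the three possible phases — and picking the phase with the
lowest third-position mean — recovers the reading frame without annotation.
Poison-exon sequence, which is not translated in the productive isoform,
shows no such dip.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree

from .intervals import GenomicInterval

#: minimum fraction of exon positions with per-base scores for a valid profile
MIN_PER_BASE_COVERAGE = 0.5


@dataclass
class ScoredElement:
    interval: GenomicInterval
    score: float


class ConservationTrack:
    """Element intervals with scores plus an optional per-base score map."""

    def __init__(
        self,
        elements: list[ScoredElement] | None = None,
        per_base: dict[str, dict[int, float]] | None = None,
    ):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.elements = elements or []
        for el in self.elements:
            self._trees[el.interval.chrom].addi(
                el.interval.start, el.interval.end, el.score
            )
        self.per_base = per_base or {}

    def elements_overlapping(self, iv: GenomicInterval) -> list[tuple[int, int, float]]:
        """(overlap_start, overlap_end, score) for elements intersecting iv."""
        out = []
        for node in self._trees[iv.chrom].overlap(iv.start, iv.end):
            out.append((max(node.begin, iv.start), min(node.end, iv.end), node.data))
        return sorted(out)

    def base_score(self, chrom: str, pos: int) -> float | None:
        return self.per_base.get(chrom, {}).get(pos)


def read_elements_bed(path: str | Path) -> list[ScoredElement]:
    """BED5 reader: chrom, start, end, name, score (0-1000 scale)."""
    elements = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 else 0.0
            elements.append(
                ScoredElement(GenomicInterval(chrom, start, end), score)
            )
    return elements


def read_per_base_bedgraph(path: str | Path) -> dict[str, dict[int, float]]:
    """bedGraph reader into a sparse position->score map per chromosome."""
    per_base: dict[str, dict[int, float]] = defaultdict(dict)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")[:4]
            val = float(value)
            for pos in range(int(start), int(end)):
                per_base[chrom][pos] = val
    return dict(per_base)


def weighted_element_score(
    exon: GenomicInterval,
    track: ConservationTrack,
    denominator: str = "intersection",
) -> float:
    """Element score of an exon, weighted by intersection length.

    Returns sum(score_i * |overlap_i|) / D over elements intersecting the
    exon, where D is the total intersected length (``denominator =
    "intersection"``, a true weighted mean of element scores) or the exon
    length (``"exon"``, which scores uncovered bases as 0).  Exons touched by
    no element score 0.
    """
    overlaps = track.elements_overlapping(exon)
    if not overlaps:
        return 0.0
    num = sum(score * (e - s) for s, e, score in overlaps)
    if denominator == "intersection":
        den = sum(e - s for s, e, _ in overlaps)
    elif denominator == "exon":
        den = exon.length
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return num / den


@dataclass
class CodonProfile:
    """Mean per-base score at codon positions 1..3 under an assigned phase."""

    means: tuple[float, float, float]
    phase: int
    source: str  # "annotation" or "inferred"

    @property
    def third_position_mean(self) -> float:
        return self.means[2]


def _exon_positions_transcribed(exon: GenomicInterval) -> list[int]:
    pos = list(range(exon.start, exon.end))
    return pos[::-1] if exon.strand == "-" else pos


def codon_position_profile(
    exon: GenomicInterval,
    track: ConservationTrack,
    phase: int,
    source: str = "annotation",
) -> CodonProfile:
    """Per-codon-position means walking the exon in transcription order.

    ``phase`` is the number of bases of the exon's first codon that belong to
    the previous exon: with phase 0 the first exon base is codon position 1,
    with phase 1 it is codon position 3, with phase 2 it is codon position 2
    (base i sits at codon position ((i - phase) mod 3) + 1).  Positions with
    missing per-base scores are excluded; fewer than half the exon covered is
    an error.
    """
    if exon.length < 3:
        raise ValueError(f"exon {exon} shorter than 3 nt has no codon structure")
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    buckets: tuple[list[float], list[float], list[float]] = ([], [], [])
    n_scored = 0
    for i, pos in enumerate(_exon_positions_transcribed(exon)):
        score = track.base_score(exon.chrom, pos)
        if score is None:
            continue
        n_scored += 1
        buckets[(i - phase) % 3].append(score)
    if n_scored < MIN_PER_BASE_COVERAGE * exon.length or any(
        not b for b in buckets
    ):
        raise ValueError(
            f"per-base scores cover {n_scored}/{exon.length} positions of {exon}; "
            f"at least {MIN_PER_BASE_COVERAGE:.0%} required"
        )
    means = tuple(statistics.fmean(b) for b in buckets)
    return CodonProfile(means=means, phase=phase, source=source)


def infer_phase(exon: GenomicInterval, track: ConservationTrack) -> CodonProfile:
    """Choose the phase whose third-position mean is lowest (ties: lowest phase)."""
    profiles = [
        codon_position_profile(exon, track, phase, source="inferred")
        for phase in (0, 1, 2)
    ]
    return min(profiles, key=lambda p: (p.third_position_mean, p.phase))


def frame_from_insertion(result, exon: GenomicInterval) -> int:
    """Phase of an inserted exon from the annotated frame downstream of it.

    The phase is back-propagated so that the annotated exon following the
    insertion keeps its annotated reading frame: if that exon's first base has
    codon index c and the inserted exon has length L, the inserted exon's
    phase is (L - c) mod 3.  Raises for insertions outside the coding span.
    """
    if result.status != "inserted":
        raise ValueError("cannot derive a frame from an incompatible insertion")
    if result.cds_start_mrna is None or result.cds_end_mrna is None:
        raise ValueError("transcript has no CDS; inserted exon has no frame")
    e0, e1 = result.exon_mrna_span
    if e1 <= result.cds_start_mrna or e0 >= result.cds_end_mrna:
        raise ValueError("insertion lies in an untranslated region; no frame")
    # The annotated exon after the insertion starts at e1 in the modified mRNA
    # and at e1 - L in the original; its annotated codon index is taken from
    # the original coordinates (cds_start is upstream of the insertion, so it
    # is unshifted).
    c_annotated = (e1 - exon.length - result.cds_start_mrna) % 3
    return (exon.length - c_annotated) % 3
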