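"""Inclusion-level (Psi) quantification and downstream selection filters.

Psi (percent spliced-in) is the two-junction split-read estimator

    Psi = (inc_up + inc_down) / (inc_up + inc_down + 2 * exc)

where inc_up/inc_down count reads over the two inclusion junctions and exc
counts reads over the skip junction; the factor 2 balances the number of
read placements supporting each outcome.  Counts are pooled across all
samples of a group before the ratio is taken, and estimates whose
denominator is below 40 reads are reported as missing.

Condition responses are plain differences (DeltaPsi = Psi_a - Psi_b); intron
retention is summarised by the splicing index I / (I + R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam

from .discovery import CassetteCandidate, CatalogEntry
from .intervals import GenomicInterval
from .junctions import JunctionTable

log = logging.getLogger(__name__)

DEFAULT_DENOMINATOR_MIN = 40


@dataclass
class PsiValue:
    exon: GenomicInterval
    group: str
    inc_upstream: int
    inc_downstream: int
    exc: int
    denominator_min: int = DEFAULT_DENOMINATOR_MIN

    @property
    def denominator(self) -> int:
        return self.inc_upstream + self.inc_downstream + 2 * self.exc

    @property
    def psi(self) -> float | None:
        if self.denominator < self.denominator_min:
            return None
        return (self.inc_upstream + self.inc_downstream) / self.denominator


@dataclass
class DeltaPsi:
    exon: GenomicInterval
    contrast: tuple[str, str]

    delta: float | None


@dataclass
class SplicingIndexValue:
    intron: GenomicInterval | None
    I: int
    R: int

    @property
    def index(self) -> float | None:
        if self.I + self.R == 0:
            return None
        return self.I / (self.I + self.R)


def compute_psi(
    junctions: JunctionTable,
    entry: CatalogEntry | CassetteCandidate,
    grouping: dict[str, str],
    denominator_min: int = DEFAULT_DENOMINATOR_MIN,
) -> list[PsiValue]:
    """Psi per group for one cassette exon, pooling counts within each group."""
    groups: dict[str, list[str]] = {}
    for sample, group in grouping.items():
        groups.setdefault(group, []).append(sample)
    out = []
    for group, samples in sorted(groups.items()):
        inc_up = junctions.pooled_count(entry.upstream_intron, samples)
        inc_down = junctions.pooled_count(entry.downstream_intron, samples)
        exc = junctions.pooled_count(entry.skip_intron, samples)
        out.append(
            PsiValue(
                exon=entry.exon,
                group=group,
                inc_upstream=inc_up,
                inc_downstream=inc_down,
                exc=exc,
                denominator_min=denominator_min,
            )
        )
    return out


def delta_psi(a: PsiValue, b: PsiValue) -> DeltaPsi:
    """DeltaPsi = Psi_a - Psi_b; missing on either side propagates."""
    if a.exon != b.exon:
        raise ValueError(f"delta_psi across different exons: {a.exon} vs {b.exon}")
    if a.psi is None or b.psi is None:
        delta = None
    else:
        delta = a.psi - b.psi
    return DeltaPsi(exon=a.exon, contrast=(a.group, b.group), delta=delta)


def splicing_index(I: int, R: int, intron: GenomicInterval | None = None) -> SplicingIndexValue:
    """Splicing index I/(I+R); missing when no informative reads exist."""
    if I < 0 or R < 0:
        raise ValueError("read counts must be non-negative")
    return SplicingIndexValue(intron=intron, I=I, R=R)


def count_retention_reads(
    alignment_file: str,
    intron: GenomicInterval,
    min_intronic_overhang: int = 6,
) -> int:
    """Reads supporting retention of an intron.

    A read supports retention when one of its contiguous aligned blocks
    crosses either exon-intron boundary with at least ``min_intronic_overhang``
    nt on the intronic side (a read spliced across the intron does not, since
    the N operation splits its blocks at the boundary).
    """
    n = 0
    with pysam.AlignmentFile(str(alignment_file), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != intron.chrom:
                continue
            blocks = read.get_blocks()
            supports = False
            for s, e in blocks:
                into_start = min(e, intron.end) - max(s, intron.start)
                crosses_donor = s < intron.start and into_start >= min_intronic_overhang
                crosses_acceptor = e > intron.end and into_start >= min_intronic_overhang
                if crosses_donor or crosses_acceptor:
                    supports = True
            if supports:
                n += 1
    return n


def per_sample_psi_matrix(
    junctions: JunctionTable,
    entries: list[CatalogEntry],
    samples: list[str],
    denominator_min: int = DEFAULT_DENOMINATOR_MIN,
) -> dict[GenomicInterval, dict[str, float | None]]:
    """Per-sample Psi for each catalog exon (groups of one sample each)."""
    matrix: dict[GenomicInterval, dict[str, float | None]] = {}
    for entry in entries:
        values = compute_psi(
            junctions, entry, {s: s for s in samples}, denominator_min=denominator_min
        )
        matrix[entry.exon] = {v.group: v.psi for v in values}
    return matrix


def _median(values: list[float]) -> float | None:
    if not values:
        return None
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    return ordered[mid] if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2


def tissue_specific_exons(
    psi_matrix: dict[GenomicInterval, dict[str, float | None]],
    sample_tissues: dict[str, str],
    min_median: float = 0.20,
) -> list[tuple[GenomicInterval, list[str]]]:
    """Exons whose per-tissue median Psi reaches ``min_median`` somewhere.

    The per-tissue statistic is the median over per-sample Psi values of that
    tissue, ignoring missing (low-denominator) samples; the comparison is
    inclusive.  Returns each flagged exon with its qualifying tissues.
    """
    flagged = []
    for exon, by_sample in psi_matrix.items():
        by_tissue: dict[str, list[float]] = {}
        for sample, psi in by_sample.items():
            if psi is None:
                continue
            by_tissue.setdefault(sample_tissues.get(sample, sample), []).append(psi)
        qualifying = sorted(
            t for t, vals in by_tissue.items()
            if (m := _median(vals)) is not None and m >= min_median
        )
        if qualifying:
            flagged.append((exon, qualifying))
    return flagged


def responsive_exons(
    delta_by_factor: dict[GenomicInterval, dict[str, float | None]],
    exon_min: float = 0.10,
    factor_min: float = 0.05,
    factor_floor: int = 10,
) -> tuple[list[GenomicInterval], list[str]]:
    """Regulated exons and regulating factors from a DeltaPsi matrix.

    Keeps exons with max |DeltaPsi| >= ``exon_min`` over factors, and factors
    with strictly more than ``factor_floor`` exons at |DeltaPsi| >=
    ``factor_min``.
    """
    exons = [
        exon
        for exon, by_factor in delta_by_factor.items()
        if any(d is not None and abs(d) >= exon_min for d in by_factor.values())
    ]
    factor_counts: dict[str, int] = {}
    for by_factor in delta_by_factor.values():
        for factor, d in by_factor.items():
            factor_counts.setdefault(factor, 0)
            if d is not None and abs(d) >= factor_min:
                factor_counts[factor] += 1
    factors = sorted(f for f, n in factor_counts.items() if n > factor_floor)
    return exons, factors


def validation_candidates(
    delta_chx: dict[GenomicInterval, float | None],
    gene_fold_change: dict[GenomicInterval, float],
    split_support: dict[GenomicInterval, int],
    d_min: float = 0.05,
    fold_min: float = 4.0,
    reads_min: int = 10,
) -> list[GenomicInterval]:
    """Exons passing all three validation filters (response, expression, support)."""
    kept = []
    for exon, delta in delta_chx.items():
        if exon not in gene_fold_change or exon not in split_support:
            log.info("validation_candidates: %s missing from an input, excluded", exon)
            continue
        if delta is None or delta < d_min:
            continue
        if gene_fold_change[exon] < fold_min:
            continue
        if split_support[exon] < reads_min:
            continue
        kept.append(exon)
    return kept
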