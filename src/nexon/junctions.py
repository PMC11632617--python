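"""Split-read junction extraction, entropy filtering and count tables.

Split reads (CIGAR N operations) evidence splice junctions.  Alignment
artifacts tend to stack reads at a single offset, so junctions are filtered
on the Shannon entropy of the read-offset distribution (default >= 1.5 bits)
and on canonical GT/AG dinucleotides, with the junction strand assigned from
which strand's dinucleotides match.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .annotation import is_canonical
from .genome import Genome
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

DEFAULT_ENTROPY_MIN = 1.5  # bits


@dataclass
class JunctionRecord:
    """Counts for one (sample, junction).

    ``offset_counts`` maps the read offset — the distance in read coordinates
    from the read 5' end to the last aligned base before the junction — to the
    number of reads observed at that offset.
    """

    junction: GenomicInterval
    sample_id: str
    offset_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.offset_counts.values())

    def add(self, offset: int, count: int = 1) -> None:
        self.offset_counts[offset] = self.offset_counts.get(offset, 0) + count

    @property
    def entropy(self) -> float:
        return offset_entropy(self.offset_counts)


def offset_entropy(offset_counts: dict[int, int]) -> float:
    """Shannon entropy (bits) of the offset distribution."""
    counts = [c for c in offset_counts.values() if c > 0]
    if not counts:
        raise ValueError("offset_entropy of an empty offset distribution")
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts)


def extract_junctions(
    alignment_file: str | Path,
    sample_id: str,
    mapq_min: int = 0,
) -> list[JunctionRecord]:
    """Collect split-read junctions from a SAM file.

    Each N operation of each read contributes one observation to the record of
    the spanned intron; the offset is measured from the read 5' end (the right
    end of the stored query for reverse-strand alignments).  Reads below
    ``mapq_min`` and reads with malformed CIGARs are skipped.
    """
    records: dict[tuple[str, int, int], JunctionRecord] = {}
    n_reads = n_skipped = 0
    with pysam.AlignmentFile(str(alignment_file), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            if read.mapping_quality < mapq_min:
                continue
            n_reads += 1
            try:
                obs = _walk_cigar(read)
            except ValueError as exc:
                n_skipped += 1
                log.warning("skipping read %s: %s", read.query_name, exc)
                continue
            for start, end, offset in obs:
                key = (read.reference_name, start, end)
                rec = records.get(key)
                if rec is None:
                    rec = records[key] = JunctionRecord(
                        GenomicInterval(read.reference_name, start, end, "+"),
                        sample_id,
                    )
                rec.add(offset)
    if n_skipped:
        log.info("%s: skipped %d/%d reads with malformed CIGARs",
                 sample_id, n_skipped, n_reads)
    return list(records.values())


# CIGAR op codes: 0=M 1=I 2=D 3=N 4=S 5=H 7== 8=X
_REF_CONSUMING = {0, 2, 3, 7, 8}
_QUERY_CONSUMING = {0, 1, 4, 7, 8}


def _walk_cigar(read) -> list[tuple[int, int, int]]:
    """(intron_start, intron_end, offset) for each N operation of the read."""
    out = []
    ref = read.reference_start
    query = 0
    query_len = sum(l for op, l in read.cigartuples if op in _QUERY_CONSUMING)
    for op, length in read.cigartuples:
        if length <= 0:
            raise ValueError(f"non-positive CIGAR length {length}")
        if op == 3:
            # offset from the 5' end of the read as sequenced
            offset = query_len - query if read.is_reverse else query
            out.append((ref, ref + length, offset))
        if op in _REF_CONSUMING:
            ref += length
        if op in _QUERY_CONSUMING:
            query += length
    return out


@dataclass
class FilterSummary:
    retained: int = 0
    dropped_entropy: int = 0
    dropped_noncanonical: int = 0
    reads_retained: int = 0
    reads_dropped: int = 0


class JunctionTable:
    """Filtered junction records keyed by (sample, junction coordinates)."""

    def __init__(self, entropy_threshold: float = DEFAULT_ENTROPY_MIN):
        self.entropy_threshold = entropy_threshold
        self._records: dict[tuple[str, tuple[str, int, int]], JunctionRecord] = {}
        self.summary = FilterSummary()

    def add(self, record: JunctionRecord) -> None:
        key = (record.sample_id, record.junction.key())
        if key in self._records:
            for off, c in record.offset_counts.items():
                self._records[key].add(off, c)
        else:
            self._records[key] = record

    def records(self) -> list[JunctionRecord]:
        return list(self._records.values())

    @property
    def samples(self) -> set[str]:
        return {s for s, _ in self._records}

    def count(self, sample_id: str, intron: GenomicInterval) -> int:
        rec = self._records.get((sample_id, intron.key()))
        return rec.total if rec is not None else 0

    def pooled_count(
        self, intron: GenomicInterval, samples: list[str] | None = None
    ) -> int:
        use = self.samples if samples is None else samples
        return sum(self.count(s, intron) for s in use)

    def __len__(self) -> int:
        return len(self._records)


def filter_junctions(
    records: list[JunctionRecord],
    genome: Genome,
    entropy_min: float = DEFAULT_ENTROPY_MIN,
) -> JunctionTable:
    """Retain junctions with offset entropy >= ``entropy_min`` and GT/AG ends.

    Strand is assigned from the dinucleotides (GT..AG -> '+', CT..AC -> '-'),
    not from alignment flags; junctions matching neither are dropped and
    counted in the table's summary.
    """
    table = JunctionTable(entropy_threshold=entropy_min)
    for rec in records:
        if rec.entropy < entropy_min:
            table.summary.dropped_entropy += 1
            table.summary.reads_dropped += rec.total
            continue
        strand = _assign_strand(rec.junction, genome)
        if strand is None:
            table.summary.dropped_noncanonical += 1
            table.summary.reads_dropped += rec.total
            continue
        rec.junction = GenomicInterval(
            rec.junction.chrom, rec.junction.start, rec.junction.end, strand
        )
        table.summary.retained += 1
        table.summary.reads_retained += rec.total
        table.add(rec)
    return table


def _assign_strand(junction: GenomicInterval, genome: Genome) -> str | None:
    for strand in ("+", "-"):
        iv = GenomicInterval(junction.chrom, junction.start, junction.end, strand)
        if is_canonical(iv, genome):
            return strand
    return None


TSV_COLUMNS = [
    "sample", "chrom", "start", "end", "strand", "total_count", "entropy", "offsets",
]


def write_junction_tsv(table: JunctionTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TSV_COLUMNS)
        for rec in sorted(table.records(), key=lambda r: (r.sample_id, r.junction)):
            offsets = ",".join(
                f"{o}:{c}" for o, c in sorted(rec.offset_counts.items())
            )
            writer.writerow([
                rec.sample_id, rec.junction.chrom, rec.junction.start,
                rec.junction.end, rec.junction.strand, rec.total,
                f"{rec.entropy:.4f}", offsets,
            ])


def read_junction_tsv(
    path: str | Path, entropy_threshold: float = DEFAULT_ENTROPY_MIN
) -> JunctionTable:
    table = JunctionTable(entropy_threshold=entropy_threshold)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rec = JunctionRecord(
                GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                row["sample"],
            )
            for pair in row["offsets"].split(","):
                off, cnt = pair.split(":")
                rec.add(int(off), int(cnt))
            table.add(rec)
            table.summary.retained += 1
            table.summary.reads_retained += rec.total
    return table
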