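"""Ortholog filters for exons lifted to another genome assembly.

Coordinate liftover itself is consumed as a pre-computed mapping table
(source interval -> target interval plus a gap flag); this module only
applies the acceptance rules — the mapping must be gap-free and both mapped
flanking introns must carry canonical GT/AG in the target genome — and
decides whether the mapped exon is expressed in the target species'
junction data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .annotation import is_canonical
from .genome import Genome
from .intervals import GenomicInterval
from .junctions import JunctionTable


@dataclass
class MappedExon:
    source_exon: GenomicInterval
    target_exon: GenomicInterval
    target_upstream_intron: GenomicInterval
    target_downstream_intron: GenomicInterval
    gap_free: bool


def accept_mapping(m: MappedExon, target_genome: Genome) -> bool:
    """True iff the mapping is gap-free and both target flanks are GT/AG."""
    if not m.gap_free:
        return False
    return is_canonical(m.target_upstream_intron, target_genome) and is_canonical(
        m.target_downstream_intron, target_genome
    )


def ortholog_expressed(
    m: MappedExon,
    target_junctions: JunctionTable,
    same_sample: bool = True,
) -> bool:
    """Whether the mapped exon is expressed in the target species.

    Default (strict) reading: some single sample must show at least one split
    read at *both* flanking junctions.  With ``same_sample=False`` each
    boundary may be supported in a different sample.
    """
    samples = target_junctions.samples
    if same_sample:
        return any(
            target_junctions.count(s, m.target_upstream_intron) >= 1
            and target_junctions.count(s, m.target_downstream_intron) >= 1
            for s in samples
        )
    return any(
        target_junctions.count(s, m.target_upstream_intron) >= 1 for s in samples
    ) and any(
        target_junctions.count(s, m.target_downstream_intron) >= 1 for s in samples
    )


def read_mapping_tsv(path: str | Path) -> list[MappedExon]:
    """Mapping table: source/target exon coordinates, target flanks, gap flag."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            strand = row["target_strand"]
            out.append(
                MappedExon(
                    source_exon=GenomicInterval(
                        row["source_chrom"], int(row["source_start"]),
                        int(row["source_end"]), row["source_strand"],
                    ),
                    target_exon=GenomicInterval(
                        row["target_chrom"], int(row["target_start"]),
                        int(row["target_end"]), strand,
                    ),
                    target_upstream_intron=GenomicInterval(
                        row["target_chrom"], int(row["target_flank_a"]),
                        int(row["target_start"]), strand,
                    ),
                    target_downstream_intron=GenomicInterval(
                        row["target_chrom"], int(row["target_end"]),
                        int(row["target_flank_b"]), strand,
                    ),
                    gap_free=row["gap_free"].lower() in ("1", "true", "yes"),
                )
            )
    return out
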