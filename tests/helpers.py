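"""Shared test utilities: toy locus builders and independent oracles.

Oracles here deliberately re-derive results through a different path than the
package (string slicing plus Biopython translation, brute-force per-base
sums, exhaustive enumeration) so agreement is meaningful.
"""

from __future__ import annotations

import random
from pathlib import Path

from Bio.Seq import Seq

from nexon.annotation import TranscriptModel
from nexon.genome import Genome, reverse_complement
from nexon.intervals import GenomicInterval


def write_fasta(path: Path, seqs: dict[str, str]) -> Genome:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return Genome(path)


def mirror_locus(seqs: dict[str, str], intervals: list[GenomicInterval]):
    """Reverse-complement every chromosome and flip interval coordinates."""
    flipped = {}
    out = []
    for name, seq in seqs.items():
        flipped[name] = reverse_complement(seq)
    for iv in intervals:
        n = len(seqs[iv.chrom])
        out.append(
            GenomicInterval(
                iv.chrom, n - iv.end, n - iv.start, "-" if iv.strand == "+" else "+"
            )
        )
    return flipped, out


def make_transcript(
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: tuple[int, int] | None = None,
    transcript_id: str = "t1",
    gene_id: str = "g1",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
    )


# ---------------------------------------------------------------------------
# independent PTC oracle


def ptc_oracle(
    genome_seq: str,
    exons: list[tuple[int, int]],
    cds: tuple[int, int] | None,
    insert: tuple[int, int],
    strand: str = "+",
    rule_nt: int = 50,
):
    """Brute-force re-derivation of the 50-nt-rule verdict.

    Rebuilds the modified mRNA by plain string slicing, maps CDS boundaries by
    scanning exon blocks, translates with Biopython to find the first stop,
    and applies the distance rule.  Returns (verdict, ptc_distance).
    """
    blocks = sorted(exons + [insert])
    if strand == "+":
        mrna = "".join(genome_seq[s:e] for s, e in blocks)
    else:
        mrna = "".join(
            str(Seq(genome_seq[s:e]).reverse_complement()) for s, e in reversed(blocks)
        )

    def mpos(gpos: int) -> int:
        ordered = blocks if strand == "+" else list(reversed(blocks))
        cum = 0
        for s, e in ordered:
            if s <= gpos < e:
                return cum + (gpos - s if strand == "+" else e - 1 - gpos)
            cum += e - s
        raise AssertionError("position not exonic")

    if cds is None:
        return "utr_5prime", None
    if strand == "+":
        cstart, cend = mpos(cds[0]), mpos(cds[1] - 1) + 1
        e0 = mpos(insert[0])
    else:
        cstart, cend = mpos(cds[1] - 1), mpos(cds[0]) + 1
        e0 = mpos(insert[1] - 1)
    e1 = e0 + (insert[1] - insert[0])
    if e1 <= cstart:
        return "utr_5prime", None
    if e0 >= cend:
        return "utr_3prime", None

    ordered = blocks if strand == "+" else list(reversed(blocks))
    last_junction = len(mrna) - (ordered[-1][1] - ordered[-1][0])
    coding = mrna[cstart:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    star = protein.find("*")
    if star == -1:
        return "coding", None
    stop_end = cstart + star * 3 + 3
    if stop_end >= cend:
        return "coding", None
    distance = last_junction - stop_end
    return ("poison" if distance >= rule_nt else "coding"), distance


def random_toy_locus(rng: random.Random):
    """A random small plus-strand gene plus a random intronic insert."""
    n_ex = rng.randint(3, 5)
    exon_lens = [rng.randint(15, 60) for _ in range(n_ex)]
    intron_lens = [rng.randint(60, 120) for _ in range(n_ex - 1)]
    pos = rng.randint(5, 20)
    exons = []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_ex - 1:
            pos += intron_lens[i]
    genome_len = pos + rng.randint(5, 20)
    seq = "".join(rng.choice("ACGT") for _ in range(genome_len))

    cds_start = exons[0][0] + rng.randint(0, exon_lens[0] - 4)
    cds_end = exons[-1][1] - rng.randint(0, exon_lens[-1] - 4)
    intron_i = rng.randint(0, n_ex - 2)
    a, b = exons[intron_i][1], exons[intron_i + 1][0]
    ilen = rng.randint(9, min(45, b - a - 10))
    x = rng.randint(a + 3, b - ilen - 3)
    insert = (x, x + ilen)
    return seq, exons, (cds_start, cds_end), insert
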