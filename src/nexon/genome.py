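"""Genome sequence access backed by an indexed FASTA (pyfaidx)."""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Random-access genome sequence.

    Fetches are 0-based half-open and always uppercase.  ``fetch`` returns the
    plus-strand (genomic) sequence; ``fetch_transcribed`` reverse-complements
    for minus-strand intervals so the result reads 5'->3' on the transcript.
    """

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        self._fasta = Fasta(str(fasta_path), sequence_always_upper=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        self._require(chrom)
        return len(self._fasta[chrom])

    def _require(self, chrom: str) -> None:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not present in {self.path}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._require(chrom)
        if start < 0 or end > len(self._fasta[chrom]) or start >= end:
            raise ValueError(
                f"invalid fetch {chrom}:{start}-{end} "
                f"(chromosome length {len(self._fasta[chrom])})"
            )
        return str(self._fasta[chrom][start:end])

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)

    def fetch_transcribed(self, iv: GenomicInterval) -> str:
        seq = self.fetch(iv.chrom, iv.start, iv.end)
        return reverse_complement(seq) if iv.strand == "-" else seq
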