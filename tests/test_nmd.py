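import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nexon.annotation import GeneModel
from nexon.genome import reverse_complement
from nexon.intervals import GenomicInterval
from nexon.nmd import (
    classify_across_transcripts,
    classify_ptc,
    insert_exon,
    is_frameshift,
)

from helpers import make_transcript, mirror_locus, ptc_oracle, random_toy_locus, write_fasta

EXONS = [(0, 100), (200, 300), (400, 500)]


def boundary_locus(distance: int, insert_len: int = 130):
    """Toy gene where the planted stop's 3' end is ``distance`` nt before the
    last junction of the modified mRNA.

    mRNA layout: E1(100) + E2(100) + X(insert_len) + E3(100); the last
    junction is at 200 + insert_len.  Background is stop-free (all A), so the
    only stops are the planted one and the annotated one (implied by cds_end).
    """
    exons = [(0, 100), (200, 300), (500, 600)]
    insert = (320, 320 + insert_len)
    seq = list("A" * 700)
    s_mrna = 200 + insert_len - distance - 3  # stop codon start, modified mRNA
    assert 200 <= s_mrna <= 200 + insert_len - 3
    cds_start = 9 + (s_mrna - 9) % 3  # keep the planted stop in frame
    gpos = 320 + (s_mrna - 200)
    seq[gpos : gpos + 3] = "TAA"
    genome_seq = "".join(seq)
    tx = make_transcript("c", "+", exons, cds=(cds_start, 580))
    return genome_seq, tx, insert


class TestFiftyNtRule:
    @pytest.mark.parametrize(
        "distance,verdict", [(120, "poison"), (50, "poison"), (49, "coding")]
    )
    def test_boundary(self, distance, verdict, tmp_path):
        genome_seq, tx, insert = boundary_locus(distance)
        genome = write_fasta(tmp_path / "g.fa", {"c": genome_seq})
        result = insert_exon(tx, GenomicInterval("c", *insert, "+"), genome)
        v = classify_ptc(result)
        assert v.verdict == verdict
        assert v.ptc_distance == distance

    def test_matches_independent_oracle(self, tmp_path):
        genome_seq, tx, insert = boundary_locus(50)
        v_oracle, d_oracle = ptc_oracle(
            genome_seq,
            [(e.start, e.end) for e in tx.exons],
            (tx.cds_start, tx.cds_end),
            insert,
        )
        assert (v_oracle, d_oracle) == ("poison", 50)


class TestInsertExon:
    def test_insertion_into_intron(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS, cds=(10, 480))
        result = insert_exon(tx, GenomicInterval("c", 320, 380, "+"), genome)
        assert result.status == "inserted"
        assert len(result.modified_exons) == 4
        assert len(result.mrna) == 360
        assert result.last_junction_mrna == 260
        assert result.exon_mrna_span == (200, 260)

    def test_exon_outside_transcript_span_incompatible(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 700})
        tx = make_transcript("c", "+", EXONS, cds=(10, 480))
        assert insert_exon(tx, GenomicInterval("c", 550, 600, "+"), genome).status == "incompatible"

    def test_exon_overlapping_transcript_exon_incompatible(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 700})
        tx = make_transcript("c", "+", EXONS, cds=(10, 480))
        assert insert_exon(tx, GenomicInterval("c", 250, 350, "+"), genome).status == "incompatible"

    def test_minus_strand_mrna_is_reverse_complement(self, tmp_path):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(600))
        seqs, ivs = mirror_locus(
            {"c": seq},
            [GenomicInterval("c", s, e, "+") for s, e in EXONS]
            + [GenomicInterval("c", 320, 380, "+")],
        )
        genome_plus = write_fasta(tmp_path / "p.fa", {"c": seq})
        genome_minus = write_fasta(tmp_path / "m.fa", {"c": seqs["c"]})
        tx_plus = make_transcript("c", "+", EXONS)
        tx_minus = make_transcript(
            "c", "-", sorted((iv.start, iv.end) for iv in ivs[:3])
        )
        r_plus = insert_exon(tx_plus, GenomicInterval("c", 320, 380, "+"), genome_plus)
        r_minus = insert_exon(tx_minus, ivs[3], genome_minus)
        assert r_minus.mrna == r_plus.mrna


class TestUtrVerdicts:
    def test_insertion_downstream_of_stop_is_3prime_utr(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS, cds=(10, 91))  # CDS ends in exon 1
        result = insert_exon(tx, GenomicInterval("c", 320, 380, "+"), genome)
        assert classify_ptc(result).verdict == "utr_3prime"

    def test_insertion_upstream_of_cds_is_5prime_utr(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS, cds=(420, 480))  # CDS in last exon
        result = insert_exon(tx, GenomicInterval("c", 120, 160, "+"), genome)
        assert classify_ptc(result).verdict == "utr_5prime"

    def test_noncoding_transcript_gives_utr_verdict(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS)
        result = insert_exon(tx, GenomicInterval("c", 320, 380, "+"), genome)
        assert classify_ptc(result).verdict.startswith("utr")

    def test_nonstop_mrna_flagged(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS, cds=(10, 480))
        result = insert_exon(tx, GenomicInterval("c", 320, 380, "+"), genome)
        v = classify_ptc(result)
        assert v.verdict == "coding" and v.nonstop


class TestFrameshift:
    @pytest.mark.parametrize("length,expected", [(94, True), (93, False), (1, True)])
    def test_lengths(self, length, expected):
        assert is_frameshift(length) is expected

    def test_non_positive_is_error(self):
        with pytest.raises(ValueError):
            is_frameshift(0)


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_frame_preserving_stop_free_exon_never_poison(seed):
    """Inclusion of a frame-preserving exon without stops cannot create a PTC."""
    import tempfile
    from pathlib import Path

    rng = random.Random(seed)
    codons = [
        a + b + c
        for a in "ACG" for b in "ACGT" for c in "ACGT"
    ]  # first base not T: never a stop, in any phase-0 reading
    n = rng.randint(4, 12)
    insert_seq = "".join(rng.choice(codons) for _ in range(n))
    seq = list("A" * 600)
    seq[320 : 320 + len(insert_seq)] = insert_seq
    seq[477:480] = "TAA"
    with tempfile.TemporaryDirectory() as tmp:
        genome = write_fasta(Path(tmp) / "g.fa", {"c": "".join(seq)})
        # cds_start chosen so the insertion point (mRNA 200) is codon-aligned:
        # the insert is then read exactly as its stop-free codons
        tx = make_transcript("c", "+", EXONS, cds=(11, 480))
        result = insert_exon(tx, GenomicInterval("c", 320, 320 + 3 * n, "+"), genome)
        assert classify_ptc(result).verdict != "poison"


class TestAcrossTranscripts:
    def gene(self, transcripts, rep="t1"):
        return GeneModel(gene_id="g1", transcripts=transcripts, representative_id=rep)

    def test_poison_in_all_coding_transcripts_is_ape(self, tmp_path):
        genome_seq, tx, insert = boundary_locus(120)
        genome = write_fasta(tmp_path / "g.fa", {"c": genome_seq})
        tx2 = make_transcript(
            "c", "+", [(e.start, e.end) for e in tx.exons],
            cds=(tx.cds_start, tx.cds_end), transcript_id="t2",
        )
        cls = classify_across_transcripts(
            GenomicInterval("c", *insert, "+"), self.gene([tx, tx2]), genome
        )
        assert cls.group == "APE"
        assert cls.mane_verdict.verdict == "poison"
        assert cls.frameshift  # 130 nt is not a multiple of 3

    def test_mixed_verdicts_give_mix(self, tmp_path):
        genome_seq, tx, insert = boundary_locus(120)
        genome = write_fasta(tmp_path / "g.fa", {"c": genome_seq})
        # second transcript whose CDS lies entirely downstream of the insert
        tx2 = make_transcript(
            "c", "+", [(e.start, e.end) for e in tx.exons],
            cds=(520, 580), transcript_id="t2",
        )
        tx3 = make_transcript(
            "c", "+", [(0, 100), (200, 300)], cds=(12, 280), transcript_id="t3"
        )
        cls = classify_across_transcripts(
            GenomicInterval("c", *insert, "+"), self.gene([tx, tx2, tx3]), genome
        )
        # tx: poison; tx2: utr_5prime (recorded, excluded); tx3: incompatible
        assert cls.per_transcript["t2"].verdict == "utr_5prime"
        assert cls.per_transcript["t3"].verdict == "incompatible"
        assert cls.group == "APE"  # only tx offers a coding context

    def test_no_coding_context_leaves_group_undefined(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"c": "A" * 600})
        tx = make_transcript("c", "+", EXONS)  # non-coding
        cls = classify_across_transcripts(
            GenomicInterval("c", 320, 380, "+"), self.gene([tx]), genome
        )
        assert cls.group is None


def test_verdicts_agree_with_oracle_on_random_toy_loci(tmp_path):
    """Exhaustive agreement with the independent translation oracle."""
    rng = random.Random(2024)
    n_checked = 0
    for i in range(100):
        seq, exons, cds, insert = random_toy_locus(rng)
        genome = write_fasta(tmp_path / f"g{i}.fa", {"c": seq})
        tx = make_transcript("c", "+", exons, cds=cds)
        result = insert_exon(tx, GenomicInterval("c", *insert, "+"), genome)
        assert result.status == "inserted"
        got = classify_ptc(result)
        want_verdict, want_distance = ptc_oracle(seq, exons, cds, insert)
        assert got.verdict == want_verdict, f"locus {i}"
        if want_verdict == "poison":
            assert got.ptc_distance == want_distance
            n_checked += 1
    assert n_checked > 5  # the sample must actually exercise the poison branch


def test_verdicts_are_strand_covariant(tmp_path):
    """Mirroring a locus to the minus strand leaves every verdict unchanged."""
    rng = random.Random(77)
    for i in range(25):
        seq, exons, cds, insert = random_toy_locus(rng)
        genome_plus = write_fasta(tmp_path / f"p{i}.fa", {"c": seq})
        tx = make_transcript("c", "+", exons, cds=cds)
        v_plus = classify_ptc(
            insert_exon(tx, GenomicInterval("c", *insert, "+"), genome_plus)
        )
        ivs = [GenomicInterval("c", s, e, "+") for s, e in exons]
        ivs.append(GenomicInterval("c", *insert, "+"))
        ivs.append(GenomicInterval("c", *cds, "+"))
        seqs_m, flipped = mirror_locus({"c": seq}, ivs)
        genome_minus = write_fasta(tmp_path / f"m{i}.fa", {"c": seqs_m["c"]})
        tx_m = make_transcript(
            "c", "-",
            sorted((iv.start, iv.end) for iv in flipped[:-2]),
            cds=(flipped[-1].start, flipped[-1].end),
        )
        v_minus = classify_ptc(insert_exon(tx_m, flipped[-2], genome_minus))
        assert (v_plus.verdict, v_plus.ptc_distance) == (
            v_minus.verdict, v_minus.ptc_distance,
        )
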