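import pytest

from nexon.annotation import AnnotationCatalog
from nexon.conservation import ConservationTrack, ScoredElement
from nexon.discovery import (
    CassetteCandidate,
    MetricVector,
    ThresholdSet,
    aggregate_catalog,
    find_cassette_exons,
    learn_thresholds,
    nearest_rank_quantile,
    score_candidate,
    select_cryptic,
)
from nexon.intervals import GenomicInterval
from nexon.junctions import JunctionRecord, JunctionTable

from helpers import make_transcript


def catalog_with(transcripts):
    from nexon.annotation import GeneModel

    genes = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return AnnotationCatalog(
        [GeneModel(gid, txs) for gid, txs in genes.items()]
    )


@pytest.fixture()
def skip_catalog():
    """Annotation providing the skip intron (1000, 2000)."""
    tx = make_transcript("chr1", "+", [(900, 1000), (2000, 2100)])
    return catalog_with([tx])


class TestFindCassetteExons:
    def test_internal_exon_with_annotated_skip_intron(self, skip_catalog):
        model = make_transcript(
            "chr1", "+", [(900, 1000), (1400, 1600), (2000, 2100)], transcript_id="m1"
        )
        (cand,) = find_cassette_exons([model], skip_catalog, "s1")
        assert (cand.exon.start, cand.exon.end) == (1400, 1600)
        assert cand.upstream_intron.key() == ("chr1", 1000, 1400)
        assert cand.downstream_intron.key() == ("chr1", 1600, 2000)
        assert cand.skip_intron.key() == ("chr1", 1000, 2000)
        assert not cand.annotated

    def test_without_annotated_skip_intron_no_candidate(self):
        empty = catalog_with(
            [make_transcript("chr1", "+", [(100, 200), (5000, 5100)])]
        )
        model = make_transcript(
            "chr1", "+", [(900, 1000), (1400, 1600), (2000, 2100)], transcript_id="m1"
        )
        assert find_cassette_exons([model], empty, "s1") == []

    def test_two_exon_model_has_no_internal_exon(self, skip_catalog):
        model = make_transcript("chr1", "+", [(900, 1000), (2000, 2100)], transcript_id="m1")
        assert find_cassette_exons([model], skip_catalog, "s1") == []

    def test_annotated_flag_for_exact_match(self):
        cassette_tx = make_transcript(
            "chr1", "+", [(900, 1000), (1400, 1600), (2000, 2100)]
        )
        skip_tx = make_transcript(
            "chr1", "+", [(900, 1000), (2000, 2100)], transcript_id="t2"
        )
        cat = catalog_with([cassette_tx, skip_tx])
        model = make_transcript(
            "chr1", "+", [(900, 1000), (1400, 1600), (2000, 2100)], transcript_id="m1"
        )
        (cand,) = find_cassette_exons([model], cat, "s1")
        assert cand.annotated

    def test_agrees_with_quadratic_brute_force(self, cohort):
        from nexon.discovery import load_assembled_models

        locus, files, _ = cohort
        models = load_assembled_models(files["s1"]["models"])[:20]
        got = {
            (c.exon.key(), c.upstream_intron.start, c.downstream_intron.end)
            for c in find_cassette_exons(models, locus.catalog, "s1")
        }
        expected = set()
        for model in models:  # quadratic oracle: test every internal exon directly
            for i, exon in enumerate(model.exons):
                if i == 0 or i == len(model.exons) - 1:
                    continue
                a = model.exons[i - 1].end
                b = model.exons[i + 1].start
                if (model.chrom, a, b) in locus.catalog.annotated_introns:
                    expected.add((exon.key(), a, b))
        assert got == expected


class TestThresholds:
    def test_nearest_rank_tenth_percentile_of_ten(self):
        values = [float(v) for v in range(10, 101, 10)]
        assert nearest_rank_quantile(values, 0.10) == 10

    def test_constant_distribution(self):
        metrics = [MetricVector(7, 7, 7)] * 12
        t = learn_thresholds(metrics, "s1")
        assert (t.conservation_min, t.coverage_min, t.split_min) == (7, 7, 7)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            nearest_rank_quantile([], 0.1)

    def test_too_few_annotated_exons_is_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            learn_thresholds([MetricVector(1, 1, 1)] * 9, "s1")


def make_candidate(exon_span, a, b, sample="s1", annotated=False, cov=None):
    x, y = exon_span
    return CassetteCandidate(
        exon=GenomicInterval("chr1", x, y, "+"),
        upstream_intron=GenomicInterval("chr1", a, x, "+"),
        downstream_intron=GenomicInterval("chr1", y, b, "+"),
        sample_id=sample,
        annotated=annotated,
        coverage_attr=cov,
    )


class TestScoreCandidate:
    def junctions(self, counts):
        table = JunctionTable()
        for (s, e), n in counts.items():
            rec = JunctionRecord(GenomicInterval("chr1", s, e, "+"), "s1")
            for i in range(n):
                rec.add(20 + i)
            table.add(rec)
        return table

    def test_split_support_is_minimum_over_flanks(self):
        cand = make_candidate((1400, 1600), 1000, 2000, cov=5.0)
        junctions = self.junctions({(1000, 1400): 12, (1600, 2000): 5})
        track = ConservationTrack([])
        m = score_candidate(cand, track, junctions)
        assert m.split_support == 5

    def test_missing_flank_gives_zero_support(self):
        cand = make_candidate((1400, 1600), 1000, 2000, cov=5.0)
        junctions = self.junctions({(1000, 1400): 12})
        m = score_candidate(cand, ConservationTrack([]), junctions)
        assert m.split_support == 0

    def test_exon_inside_single_element_scores_element(self):
        cand = make_candidate((1400, 1600), 1000, 2000, cov=5.0)
        track = ConservationTrack(
            [ScoredElement(GenomicInterval("chr1", 1300, 1700), 500.0)]
        )
        m = score_candidate(cand, track, self.junctions({}))
        assert m.conservation == 500.0

    def test_coverage_fallback_to_track_and_error_without_source(self):
        cand = make_candidate((1400, 1402), 1000, 2000)
        cov_track = {"chr1": {1400: 4.0, 1401: 6.0}}
        m = score_candidate(
            cand, ConservationTrack([]), self.junctions({}), coverage_track=cov_track
        )
        assert m.coverage == 5.0
        with pytest.raises(ValueError, match="1400"):
            score_candidate(cand, ConservationTrack([]), self.junctions({}))


class TestSelectCryptic:
    thresholds = ThresholdSet(
        conservation_min=100, coverage_min=2, split_min=4, percentile=0.1, sample_id="s1"
    )

    def test_passing_candidate_kept(self, skip_catalog):
        scored = [(make_candidate((1400, 1600), 1000, 2000), MetricVector(300, 5, 8))]
        assert len(select_cryptic(scored, self.thresholds, skip_catalog)) == 1

    def test_one_bp_overlap_with_annotated_exon_dropped(self, skip_catalog):
        # annotated exon (900, 1000); candidate overlapping by 1 bp at 999
        scored = [(make_candidate((999, 1600), 900, 2000), MetricVector(300, 5, 8))]
        assert select_cryptic(scored, self.thresholds, skip_catalog) == []

    def test_below_threshold_dropped(self, skip_catalog):
        scored = [(make_candidate((1400, 1600), 1000, 2000), MetricVector(99, 5, 8))]
        assert select_cryptic(scored, self.thresholds, skip_catalog) == []

    def test_annotated_candidate_excluded(self, skip_catalog):
        scored = [
            (
                make_candidate((1400, 1600), 1000, 2000, annotated=True),
                MetricVector(300, 5, 8),
            )
        ]
        assert select_cryptic(scored, self.thresholds, skip_catalog) == []


class TestAggregate:
    def table_with(self, counts):
        table = JunctionTable()
        for (sample, s, e), n in counts.items():
            rec = JunctionRecord(GenomicInterval("chr1", s, e, "+"), sample)
            rec.add(30, n)
            table.add(rec)
        return table

    def test_pair_with_highest_pooled_support_chosen(self):
        m = MetricVector(300, 5, 8)
        p1 = make_candidate((1400, 1600), 1000, 2000, sample="s1")
        p2 = make_candidate((1400, 1600), 900, 2000, sample="s2")
        table = self.table_with(
            {
                ("s1", 1000, 1400): 8, ("s1", 1600, 2000): 9,
                ("s2", 900, 1400): 3, ("s2", 1600, 2000): 9,
            }
        )
        catalog = aggregate_catalog([[(p1, m)], [(p2, m)]], table, {"s1": "brain", "s2": "liver"})
        (entry,) = catalog.entries
        assert entry.upstream_intron.start == 1000
        assert entry.pooled_support == 8
        assert entry.supporting_samples == ["s1", "s2"]
        assert entry.supporting_tissues == ["brain", "liver"]

    def test_tie_broken_by_shorter_skip_then_leftmost(self):
        m = MetricVector(300, 5, 8)
        p1 = make_candidate((1400, 1600), 900, 2100, sample="s1")
        p2 = make_candidate((1400, 1600), 1000, 2000, sample="s2")
        table = self.table_with(
            {
                ("s1", 900, 1400): 5, ("s1", 1600, 2100): 5,
                ("s2", 1000, 1400): 5, ("s2", 1600, 2000): 5,
            }
        )
        catalog = aggregate_catalog([[(p1, m)], [(p2, m)]], table, {})
        (entry,) = catalog.entries
        assert (entry.upstream_intron.start, entry.downstream_intron.end) == (1000, 2000)
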