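# nexon

Discovery and NMD classification of cryptic cassette exons from RNA-seq.

Most mammalian genes harbour unannotated ("cryptic") cassette exons inside
their introns. Many of these are **poison exons**: their inclusion shifts or
interrupts the reading frame, introduces a premature termination codon (PTC)
and routes the transcript into nonsense-mediated decay (NMD). `nexon`
implements a conservation-guided pipeline that finds such exons in assembled
transcript models, quantifies their inclusion, and decides whether each one
is poison or protein-coding — together with a fully synthetic data generator
so the whole pipeline is testable without any external downloads.

The package is aimed at computational RNA biologists who have per-sample
assembled transcripts (StringTie-style GTF), spliced alignments (SAM), a
reference annotation with a representative transcript per gene, and
conservation tracks, and who want a reproducible, parameterised
re-implementation of the catalog-building and classification logic.

## Method

**Discovery.** An internal exon `[x, y)` of an assembled model is a cassette
exon when its flanking introns `[a, x)` and `[y, b)` bracket an annotated
intron `[a, b)`. Split reads over junctions are counted from SAM `N` CIGAR
operations and filtered on the Shannon entropy of the read-offset
distribution (≥ 1.5 bits) and canonical GT/AG dinucleotides. Each candidate
is scored with three metrics — element conservation weighted by intersection
length, mean read coverage, and split-read support (the minimum over the two
inclusion junctions) — and kept when all three exceed per-sample thresholds
set at the 10th percentile of the same metrics over *annotated* cassette
exons. Candidates are aggregated across samples and purged of anything
overlapping an annotated exon.

**Inclusion.** Percent-spliced-in is the two-junction estimator

    Ψ = (inc_up + inc_down) / (inc_up + inc_down + 2·exc)

with counts pooled within each group and estimates discarded when the
denominator is below 40 reads. Condition responses are ΔΨ = Ψ_a − Ψ_b
(e.g. NMD inhibition by cycloheximide vs control); intron retention is
summarised by the splicing index I/(I+R).

**Classification.** Each catalog exon is spliced into every transcript of
its host gene, the mRNA is rebuilt from genomic sequence and translated from
the annotated start. Under the **50-nt rule**, a stop whose 3' end lies at
least 50 nt upstream of the last exon–exon junction is a PTC and the exon is
*poison*; exons are also labelled APE / APC / MIX according to whether they
are poison in all, none, or some of the gene's transcripts, with
UTR-resident insertions accounted separately. Codon-level conservation
profiles (third-position dips in phyloP-style scores) let the reading frame
be inferred independently of the annotation.

## Worked example

Generate the default synthetic cohort (20 genes, 15 planted cryptic exons of
known class, 5 low-conservation decoys, 8 samples at depth 100 including an
NMD-inhibition condition) and run the full pipeline:

```python
from nexon import SimulationConfig, default_cohort_design, generate_cohort
from nexon.pipeline import PipelineConfig, run_pipeline, class_proportions, group_counts

out = "example"
locus, files = generate_cohort(SimulationConfig(), default_cohort_design(depth=100),
                               out, seed=1)
result = run_pipeline(PipelineConfig(
    annotation_gtf=str(locus.gtf_path),
    genome_fasta=str(locus.genome_path),
    alignments_dir=f"{out}/samples",
    models_dir=f"{out}/samples",
    elements_bed=f"{out}/elements.bed",
    per_base_bedgraph=f"{out}/phylo.bedgraph",
    design_tsv=f"{out}/design.tsv",
    out_dir=f"{out}/results",
))
print("catalog exons:", len(result.catalog))
print("class proportions:", class_proportions(result.classifications))
print("APE/APC/MIX:", group_counts(result.classifications))
```

prints

```
catalog exons: 14
class proportions: {'poison': 0.79, 'coding': 0.14, 'non_coding': 0.07}
APE/APC/MIX: {'APE': 11, 'APC': 2, 'MIX': 0, 'undefined': 1}
```

i.e. 14 of the 15 planted exons are recovered (none of the decoys are), and
the recovered set splits into ~79% poison, 14% protein-coding and 7%
non-coding against the representative transcript. The median ΔΨ of the
catalog under NMD inhibition in this cohort is +0.216, reflecting the
stabilisation of poison-exon isoforms when decay is blocked. The same
stages are available from the shell via `nexon simulate`, `nexon junctions
count`, `nexon annotation validate` and `nexon run --config <yaml>`.

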