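# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based closed convention at the file boundary. A cassette exon `[x, y)` has
flanking introns `[a, x)`, `[y, b)` and skip intron `[a, b)`.

Transcripts are ordered exon chains with an optional coding span. The span
(`cds_start`, `cds_end`) **includes the stop codon**; the GTF reader merges
`CDS` and `stop_codon` features into this span, and the writer splits the
terminal three coding nucleotides back out as `stop_codon` features, so
Ensembl-style files round-trip. The representative ("MANE-like") transcript
of a gene is marked by a GTF `tag` attribute (default value `MANE_Select`),
overridable per gene; synthetic annotations use the same marker.
Strand-ambiguous (`.`) transcripts are rejected — every downstream step is
strand-aware. Only GT/AG introns count as canonical; GC/AG is deliberately
excluded.

The annotation is taken from a single GTF. Users who want a union of several
annotation sources should merge them beforehand.

## Junction counting

Split reads are taken from `N` CIGAR operations; each operation contributes
one observation to its intron's record, so a read with two `N` operations
supports two junctions. The *offset* of an observation is the distance in
read coordinates from the read's 5' end to the last aligned base before the
junction (for reverse-strand alignments the 5' end is the right end of the
stored query). This is one self-consistent definition of a splice-site
offset; exact equivalence with any particular external counting tool is not
claimed. Offset entropy is Shannon entropy in bits (base-2 logarithm), so
the default threshold of 1.5 is meaningful as "more than ~3 effectively
distinct offsets". Junction strand is assigned from the dinucleotides
(GT..AG → `+`, CT..AC → `-`), never from alignment flags; junctions matching
neither are dropped and tallied. The MAPQ floor defaults to 0 (count
everything) and is configurable.

## Discovery thresholds

Per-sample thresholds are the nearest-rank lower quantile (k-th smallest,
k = ⌈q·n⌉) of each metric over the annotated cassette exons of that sample —
deterministic and well-defined for integer-valued support counts. Annotated
cassette exons with zero coverage in a sample are excluded from threshold
learning (an unexpressed exon carries no information about that sample's
metric scale); at least 10 scored exons are required or the sample is
unusable. The conservation score of an exon is the element-score mean
weighted by intersection length; the denominator is the total intersected
length by default (a true weighted mean), with the alternative
(exon length, scoring uncovered bases 0) available as a switch since both
readings are defensible. No overlapping element gives score 0, the most
conservative choice for a lower-bound filter. The exon-overlap purge is
same-strand with a ≥1 bp overlap; a strand-blind mode exists. When an exon
is seen with several flanking-intron pairs, the pair with the highest pooled
split-read support wins; ties go to the shorter skip intron, then the
leftmost boundary, purely for determinism. Multi-exon skips and alternative
5'/3' splice sites are out of scope by construction.

## Inclusion quantification

Ψ uses the standard two-junction estimator
`(inc_up + inc_down) / (inc_up + inc_down + 2·exc)`; the factor 2 balances
the two read placements that evidence inclusion against the one that
evidences skipping. Counts are pooled across the samples of a group
*before* the ratio is taken, which makes the estimate invariant to how the
group is partitioned. Estimates with denominator < 40 reads are reported as
missing and excluded from all downstream statistics. Tissue specificity is
judged on per-sample Ψ values reduced to a per-tissue median (missing values
dropped), flagged when any tissue reaches 0.20. All stated thresholds are
inclusive (≥) except the regulator floor "more than ten exons", which is
strict. Retention support for the splicing index counts contiguous
alignments crossing either exon–intron boundary with at least 6 nt on the
intronic side (configurable); the boundary-crossing definition avoids
scanning whole introns and is robust to partial intron coverage.

## PTC classification (50-nt rule)

An exon is spliced into a transcript only when it lies strictly inside one
intron; anything else (overlap with an exon, outside the span, wrong
chromosome or strand) is *incompatible*, which is a value, not an error.
The modified mRNA is rebuilt from genomic sequence (reverse-complemented for
minus-strand genes) and translated codon-by-codon from the annotated start
using the standard nuclear code. The PTC distance is measured from the stop
codon's **3' end** to the last exon–exon junction, and "at least 50 nt" is
inclusive: distance ≥ 50 → poison. The junction-relative measurement
follows the mechanistic picture of the rule — an exon junction complex
sitting downstream of the terminating ribosome triggers decay — and the
inclusive boundary reads the rule literally. The annotated stop codon is
never treated as a PTC, even when a frameshift makes translation terminate
downstream of it; only stops strictly upstream of the annotated stop are
candidates. mRNAs whose translation never terminates are reported coding
with a `nonstop` flag. Insertions upstream/downstream of the coding span
yield `utr_5prime`/`utr_3prime`; insertions into transcripts with no CDS at
all are reported as `utr_5prime` by convention (the whole transcript is
untranslated), and all UTR verdicts are excluded from the APE/APC/MIX
dichotomy while remaining in the per-transcript table. The dichotomy is
taken over *all* transcripts of the host gene in the provided annotation
that offer a coding context.

## Conservation and phase inference

Per-base profiles walk the exon in transcription order. Phase φ means the
exon's first base completes a codon begun φ bases earlier, so base *i* sits
at codon position `((i − φ) mod 3) + 1`. Phase inference evaluates all
three phases and keeps the one with the lowest third-position mean —
protein-coding sequence is least constrained at the wobble position — with
ties broken to the lowest phase index. Missing per-base scores are excluded
from the means rather than imputed, and a profile is only valid when at
least half the exon's positions are scored. Annotation-derived frames are
back-propagated from the annotated exon *following* the insertion, so a
frameshifting exon takes the phase that restores the downstream annotated
frame.

## Cross-species rules

Liftover is consumed as a pre-computed mapping table. A mapping is accepted
only when gap-free and when both mapped flanking introns are GT/AG in the
target genome. "Expressed in the other species" defaults to the strict
reading — at least one split read at *both* boundaries within a single
sample — with the laxer reading (each boundary in some, possibly different,
sample) available behind a flag, since the requirement is ambiguous between
the two.

## Synthetic cohorts

The generator builds 20 genes by default (4–7 exons of 90–150 nt, introns
300–600 nt, valid ORFs, both strands, two chromosomes), each with a skip
isoform that makes one internal exon an annotated cassette exon, and plants
one event per gene: 11 poison, 3 coding and 1 UTR cryptic exon (the ~73/20/7
split) plus 5 low-conservation decoys that exercise the filters'
specificity. Poison plants carry an engineered in-frame stop ≥ 50 nt
upstream of the final junction; coding plants are frame-preserving and
stop-free (partial boundary codons are C-padded, since no stop codon
contains C); every non-decoy plant is verified against the package's own
classifier at generation time. Planted inclusion levels are drawn per
tissue, uniform on (0.25, 0.75) for cryptic exons and (0.05, 0.95) for
annotated cassettes, so learned thresholds sit below typical plant support.
Junction counts are binomial given the per-event depth (default 100 reads),
with optional beta overdispersion; the NMD-inhibition condition multiplies
the inclusion *odds* of poison exons by 3 (ΔΨ ≈ 0.2 at mid inclusion,
the magnitude seen for validated poison exons). Reads are single-end 150 nt
with uniformly drawn junction offsets, so simulated junctions pass the
entropy filter from depth ~4 upward. Element scores are Normal(520, 100)
for annotated exons, Uniform(500, 900) for plants and Uniform(5, 80) for
decoys and intron background; per-base scores are 3.0 ± 0.5 with a 1.5-unit
third-position dip over coding sequence only. The per-base track covers
exon positions only.

The generator emulates junction/coverage counts, not sequencing: there are
no base errors, no fragment-length model, no multi-mapping, no expression
variation beyond the binomial draw, and assembled models are derived from
the truth rather than from reads. Passing tests therefore demonstrate the
correctness of the pipeline's logic and estimators under its stated
assumptions, not robustness to alignment or assembly artifacts in real
data.

## Problem sizes and determinism

The default analyses use the 20-gene cohort with 8 samples at depth 100;
the NMD-response study uses 130 genes (104 poison plants) with 2 control
and 2 treated samples at depth 150; estimator calibration uses 200
replicates per true Ψ at a pooled denominator of 1600 reads; phase-inference
calibration uses 200 exons. These sizes give stable statistics while
keeping any run to seconds. Every stage is a pure function of inputs,
configuration and seed: rerunning with the same seed reproduces outputs
byte-for-byte.

## Known limitations

- Single-annotation input; no GFF3, no trans-splicing or fusion transcripts.
- BAM/CRAM, duplicate marking and multi-mapper reweighting are out of scope
  (plain SAM only).
- NMD efficiency, EJC occupancy and degradation kinetics are not modelled;
  the 50-nt rule is applied as a hard boundary.
- Gene-level expression changes are consumed as a table, not computed from
  reads.
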