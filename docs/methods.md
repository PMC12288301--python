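# Methods

## Problem and approach

Differential exon usage (DEU) analysis asks whether the *relative* usage of
parts of a gene changes between conditions — a count-level proxy for
differential splicing.  The classical workflow counts reads into flattened
(merged) exon bins; a read whose alignment bridges an intron then increments
*both* flanking exons, inflating counts and library sizes, and events that
leave the flattened exons unchanged (alternative splice sites, retained
introns) are invisible.

`deju` implements differential exon-junction usage (DEJU): exon–exon
junctions become features alongside internal exons, and each sequenced
fragment is assigned to **exactly one** feature.  The package contains the
whole desk-scale study around that idea: a splicing-event simulator, the
dual-mode quantifier, the moderated linear-model usage test with gene-level
aggregation, and the benchmark harness that measures empirical FDR and
power.

## Synthetic transcriptome

Each gene is a chain of `n_exons ~ U{4..12}` exons with lengths
`U{80..300}` bp and introns `U{200..2000}` bp, placed non-overlapping on
synthetic chromosomes.  Two isoforms per gene differ by one of four
patterns (equal proportions among the genuinely differential genes):

* **ES** — isoform B skips a random internal exon;
* **MXE** — isoform A omits internal exon *i+1* and B omits exon *i*
  (the leftmost eligible adjacent internal pair);
* **ASS** — isoform B truncates one internal splice site inward by
  `δ ~ U{30..100}` bp (bounded so at least 30 exonic bases remain).  The
  flattened exons of the gene are *unchanged*; only a junction moves.  This
  makes ASS the canonical blind spot of exon-only counting;
* **IR** — isoform B fuses two adjacent exons and the intron between them
  into one block, so B lacks exactly one junction of A.

Genes not labelled as differential receive the same two-isoform structure
without any group effect, so the null set contains realistic multi-isoform
genes with stable usage.  A five-transcript mode adds up to three extra
isoforms per gene that skip internal exons far from the event and never
carry its junctions.

The **counting annotation** (flattened exon bins and the junction database)
is built from each gene's *full reference chain*, not from the simulated
isoforms.  This emulates quantification against a reference annotation that
does not know about the events: skip/shift junctions appear as *novel*
junctions discovered from the reads (as STAR's two-pass mode would), and
retained-intron reads fall outside every exon bin and go unassigned.
Flattening the isoforms instead would make the retained intron exonic and
hide exactly the phenomenon the method targets.

## Expression and fragments

Baseline transcript proportions follow Zipf's law with exponent `s = 1`
over a random ranking of all transcripts.  For each genuinely differential
gene, isoform A's baseline is multiplied by a fold-change of 3 in group 1
and isoform B's in group 2.  Biological variation multiplies every
transcript-by-sample expectation by an independent mean-one gamma draw with
coefficient of variation `bcv = 0.2` (shape `1/bcv²`, scale `bcv²`), after
which sample columns are renormalised.  Null simulations hold the
underlying abundances fixed across replicates: no fold-change *and* no
gamma noise, so only multinomial sequencing noise remains.

Per sample, fragment counts per transcript are multinomial at the library
size (default 5·10⁶ at the desk scale; the balanced full-size study uses
5·10⁷).  Fragment length is truncated-normal (mean 250, sd 40) bounded by
twice the 75 bp read length and the transcript length; the start is
uniform.  Mates are the first and last 75 bases of the fragment, projected
exactly through the exon chain to genomic blocks — the simulator replaces
alignment by exact projection, so read placement is error-free by
construction.  Transcript coordinates run in genomic order on both strands;
classification depends only on the two mate intervals, which makes this
equivalent to strand-aware projection.

## Counting rules

In DEJU mode a fragment with at least one junction-bridging mate (≥ 1 bp on
each side of the intron) is assigned to the bridged junction with the
longest minimum overhang, ties broken by leftmost intron start.  Any other
fragment goes to the single flattened exon with the largest total overlap
across both mates, ties leftmost; fragments overlapping no bin are
unassigned.  Junctions are attributed to genes by exact match against the
junction database, or — for novel junctions — by containment of both
flanking exonic bases in exactly one gene's span.  Junction features whose
support pooled over all samples is not strictly greater than 3 reads are
dropped and their fragments become unassigned.  Library sizes are the
per-sample assigned totals, so they track the true sequencing depth up to
the unassigned fraction.

DEU mode reproduces the legacy behaviour for contrast: only exon bins
exist and a fragment increments every bin either mate overlaps, so
junction-bridging fragments are double-counted.

Two implementations of the rules exist — a per-record reference path
operating on explicit genomic blocks and a vectorised columnar path used at
scale — and the test-suite asserts their exact agreement on simulated data
in both modes.

## Statistics

Features with low counts are removed: a feature is kept when its CPM
reaches the equivalent of 10 reads in the median-sized library in at least
`ceil(0.7 × smallest group size)` samples and its total count is ≥ 15.
TMM normalisation follows the standard recipe (reference sample by 75th
percentile; 30 % / 5 % two-sided trims on M and A; inverse asymptotic
binomial variance weights; unit geometric mean) and is cross-checked
against edgeR's `calcNormFactors` in the tests.  Counts enter the model as
`log2((count + 0.5) / (lib·factor + 1) × 10⁶)`.

Per feature, OLS on the two-group design gives the log-fold-change `β`,
residual variance `s²` on `n−2` df and unscaled variance `v = 1/n₁+1/n₂`.
Empirical-Bayes moderation estimates the variance prior `(d₀, s₀²)` by
digamma/trigamma moment matching on `log s²`; when the trigamma equation
has no positive solution the prior is degenerate and the pooled mean
variance is used.  The usage contrast is `δ_j = β_j − Σw β / Σw` with
`w = 1/v`, `Var(δ_j) = s̃_j²(v_j − 1/Σw)`, and the moderated t on
`d + d₀` df.  Gene-level summaries are the Simes combination
`min_k (J·p_(k)/k)` and `F = Σt²/(J−1)` on `(J−1, d+d₀)` df, each BH-
adjusted across genes separately.  Genes with a single surviving feature
are reported untested (NA), not as p = 1.  No precision weights (voom-style)
are applied; the engine is validated by null calibration rather than by
fidelity to any existing package's internals.

## Benchmark and problem sizes

The full-size study (5000 genes, 1000 differential, 50 M fragments/sample,
20 runs) is reproduced at a 1/10 linear scale — 500 genes, 124 differential
(31 per pattern; 124 rather than 125 keeps the four patterns exactly
balanced), 5 M fragments per sample — which preserves per-gene coverage,
the quantity the operating characteristics actually depend on.  The
benchmark derives per-run seeds from a master seed by a counter scheme
(`master·10⁴ + cell·10² + run`) and averages empirical FDR and per-pattern
power per design cell.  Null calibration pools twenty null-mode runs at a
2 M library.

## What the simulation does and does not show

Fragments carry their exact origin: there is no sequence content, no
sequencing error, no mapping ambiguity.  Consequences observed in the
package's own benchmark output:

* Empirical FDR of the DEJU/Simes pipeline stays well below the nominal
  0.05, and ES/MXE power is essentially 1 at this coverage.
* ASS power is also ~1 — *higher* than in a real aligner-based pipeline,
  where junction reads with short overhangs at shifted splice sites are
  lost or misplaced.  Exact projection removes that loss mechanism.
* IR power is limited by isoform imbalance, not by mapping: when Zipf gives
  isoform B a much lower baseline than A, the lost junction tracks the gene
  average and the event is unidentifiable at any depth.  With independent
  Zipf ranks per isoform this affects roughly a fifth of IR genes at n = 3
  and shrinks with sample size.
* Gene-level Simes p-values under the null are mildly conservative in the
  body of the distribution (pooled KS against U(0,1) ≈ 0.03) because the
  usage contrasts within a gene are negatively correlated by the zero-sum
  constraint; the tail behaviour that drives FDR control is accurate, and
  feature-level p-values are uniform (KS ≈ 0.015).

## Numerical and degenerate-input choices

Book-ended exons merge during flattening (configurable).  Genes mixing
chromosomes or strands are rejected.  Transcripts shorter than the read
length are excluded from sampling with a warning; transcripts shorter than
two read lengths yield full-length fragments with overlapping mates.  A
fragment whose mates bridge different junctions takes the junction with the
larger minimum overhang (leftmost on ties) — any deterministic rule
preserves the unique-assignment invariant.  TMM falls back to factor 1
(with a warning) when fewer than ten features survive trimming.  All
randomness flows from explicit seeds; identical configurations reproduce
byte-identical outputs.

## Known limitations

No BAM/SAM input (the fragment table is the interop surface); two-group
designs only; no voom weights or robust moderation; single-process
execution.  The simulator's idealised mapping means absolute power numbers
for alignment-sensitive events (ASS) upper-bound what a real pipeline
achieves, while the counting rules, filtering and statistics are the same
as at full scale.
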