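# deju — differential exon-junction usage at desk scale

`deju` is a Python toolkit for studying **differential exon-junction usage
(DEJU)**: testing whether the relative usage of exons *and* exon–exon
junctions within a gene changes between two conditions, as a count-level
readout of differential splicing in bulk RNA-seq.

Classical differential exon usage (DEU) counts reads into flattened exon
bins.  A junction-spanning read then contributes one count to **both**
flanking exons (double counting), and splicing events that do not change the
flattened exons — alternative 3′/5′ splice sites (ASS) and intron retention
(IR) — are invisible.  DEJU fixes both problems by making junctions
first-class features and assigning each paired-end fragment to **exactly
one** feature: the bridged junction with the longest minimum overhang, or
otherwise the exon bin with the largest overlap.

The package implements the complete simulation study around this idea:

* `deju.annotation` — GTF parsing, flattened merged exons, the
  transcript-derived junction database, SAF / SJ.out.tab-style I/O;
* `deju.splice_sim` — synthetic multi-isoform transcriptomes with injected
  ES / MXE / ASS / IR events and ground-truth labels;
* `deju.read_sim` — Zipf baseline expression, gamma biological variation,
  a reciprocal isoform fold-change of 3, and exact paired-end fragment
  placement (75 bp mates);
* `deju.quantify` — DEJU counting and the legacy double-counting DEU mode,
  junction support filtering (> 3 pooled reads) and junction-to-gene
  assignment;
* `deju.preprocess` — expression filtering, TMM normalisation, log-CPM;
* `deju.dsstat` — moderated linear models (empirical-Bayes variance
  shrinkage), per-feature usage contrasts, gene-level Simes and F tests
  with BH adjustment;
* `deju.bench` / `deju.workflow` — the FDR/power benchmark harness and a
  manifest-writing pipeline, exposed through the `deju` command line.

## The statistic

For feature *j* of a gene with *J* features, OLS of log-CPM on the
two-group design gives a log-fold-change β̂ⱼ with moderated variance s̃ⱼ²
(prior estimated by digamma/trigamma moment matching).  The usage contrast
is

    δⱼ = β̂ⱼ − (Σ wβ̂)/(Σ w),   w = 1/v,   v = 1/n₁ + 1/n₂
    tⱼ = δⱼ / √( s̃ⱼ² (v − 1/Σw) )   on  d + d₀ df.

Gene-level p-values are the Simes combination `min_k (J·p₍ₖ₎/k)` and an
F-type statistic `Σt²/(J−1)`, each followed by Benjamini–Hochberg
adjustment across genes.

## Worked example

```python
import numpy as np
from deju import SimConfig, SampleDesign
from deju.workflow import run_single
from deju.bench import evaluate_detection

res = run_single(
    11,
    sim=SimConfig(n_genes=500, n_true_deu=124, seed=11),
    design=SampleDesign(n_per_group=3, library_size=5_000_000),
    modes=("DEJU", "DEU"),
)
for mode in ("DEJU", "DEU"):
    ev = evaluate_detection(res.gene_stats[mode], res.truth, 0.05, "simes")
    print(mode, round(ev.fdr, 3), {k: round(v, 3) for k, v in sorted(ev.power.items())})
```

prints (one 1/10-scale run, 3 replicates per group):

```
DEJU 0.041 {'ASS': 1.0, 'ES': 1.0, 'IR': 0.742, 'MXE': 1.0}
DEU 0.017 {'ASS': 0.0, 'ES': 0.903, 'IR': 0.0, 'MXE': 1.0}
```

Reading: with junction features the pipeline keeps the empirical FDR under
the nominal 0.05 while detecting essentially all exon-skipping,
mutually-exclusive-exon and splice-site events and most intron retentions;
with legacy exon-only counting, ASS and IR events are undetectable and the
skipped-exon power drops.  The same pair of runs shares one simulated
fragment set, so the comparison is paired.

The same study is available from the shell:

```bash
deju benchmark --seed 1 --n-runs 3 --scale 0.1 -o scratch/bench
deju pipeline -o scratch/demo --n-genes 100 --library-size 500000 --seed 7
```

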