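# spongetx

Analysis pipeline for a four-stage developmental transcriptome profiled
**without biological replicates** — the setting of early genome-wide studies of
the pelagobenthic life cycle in marine invertebrates (a free-swimming larva
settles and metamorphoses into a sessile benthic adult). One RNA library per
stage means classical replicate-based statistics are unavailable; every
detection and differential-expression decision must instead be calibrated
against the *technical* sampling noise of counting reads.

The package is aimed at bioinformaticians who want that replicate-free
calibration logic as tested, reusable code: read attribution against gene
models, depth normalization, noise-gated detection and differential
expression, resampling term enrichment, stage enrichment of gene families,
and qPCR cross-validation — plus a synthetic-data generator with planted
ground truth so the whole pipeline can be exercised and scored end to end.

## The model

Counting reads for a transcript is a Poisson-like sampling process: between
technical replicates a count `N` fluctuates on the scale of `√N`, and the
variation stays inside a conservative envelope `k·√N` with `k = 5`. The
relative error `k·√N / N` shrinks as expression grows, which yields the
pipeline's decision rules:

* **Detection** — after rescaling every library to a reference depth
  (`counts × total_mapped(ref) / total_mapped(sample)`), the detection
  threshold is the smallest count `c` such that every transcript at `≥ c` in
  one technical replicate is seen (`≥ 1` read) in the other.
* **Stage-specific expression** — per gene, each focal stage is compared with
  the mean of the other three by a two-tailed t-test on `log2(count + 1)`
  (df = 2), gated by a fold cutoff (default 4, chosen above the fold changes
  that pure replicate noise can produce).
* **Transitions** — between successive stages a gene is up/down only if the
  fold change passes the cutoff *and* `|n₂ − n₁| > 5·√max(n₁, n₂)`.
* **Enrichment** — term over-representation in a gene set is scored against
  `R` equal-sized random draws from the detected annotated universe,
  `p = (b + 1)/(R + 1)`, Benjamini–Hochberg corrected; stage enrichment of a
  gene family uses Fisher's exact test on the genes whose expression at a
  stage reaches the top 25 % of their own range.
* **qPCR validation** — relative expression by the ΔΔCt method
  (`fold = 2^(−ΔΔCt)` against a reference gene and stage), one-way ANOVA with
  Bonferroni post-tests across stage replicates, and Pearson/Spearman
  concordance between qPCR and sequencing profiles.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic dataset (2,000 genes, four stages at depths proportional to
112.5k/82.5k/50k/100k reads, 50,000 mapped reads, planted expression classes
and enriched terms):

```bash
python analysis/01_simulate.py
python analysis/02_attribute_reads.py
python analysis/03_detect.py
python analysis/04_differential_expression.py
python analysis/05_enrichment.py
python analysis/06_qpcr_concordance.py
```

Output of the attribution and detection steps:

```
read attribution (observed vs configured):
  exon         80.73%   (configured 80.7%)
  intron        5.64%   (configured 5.7%)
  intergenic   13.63%   (configured 13.6%)
placement labels recovered exactly for 100.00% of reads
intergenic reads within 10 kb of a gene: 90.5%; sense-oriented: 54.7%

replicate-calibrated raw threshold at lowest depth: 9 (~20 after normalization to PRE)
detected at >= 64 normalized reads: 476/2000 genes in >= 1 stage; 46 in all four stages
```

Read attribution recovers the generator's planted exon/intron/intergenic
placements exactly, and the intergenic reads sit mostly within 10 kb of gene
boundaries with a sense-strand excess — the signature of unannotated UTRs.
Downstream, the four-fold analysis calls 247 stage/settlement-specific and
286 transition-regulated genes (a subset of the 342 found at two-fold), with
direction accuracy 1.000 and no calls on planted-null genes; the qPCR panel
agrees with sequencing (pooled Spearman −0.92 between Ct and log2 counts;
78 % of genes with Pearson r ≥ 0.70 between the two fold profiles).

The same pipeline runs behind one command with a JSON config:

```bash
spongetx run --config configs/default_synth.json --out results/run
```

Every output is TSV/JSON/bedGraph, and two runs with the same config and seed
are byte-identical.

## Layout

```
src/spongetx/      library: io_models, read_attribution, noise_detection,
                   differential_expression, enrichment, qpcr_validation,
                   synthetic_data, pipeline, cli
analysis/          numbered narrative drivers over the library
configs/           pipeline configs (default synthetic study)
scripts/           acceptance recomputation
docs/methods.md    model, parameters, generator scope, design choices
tests/             pytest suite (unit, property and end-to-end checks)
```
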