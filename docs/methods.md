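# Methods

## Setting and model

The pipeline targets expression profiling of one organism across four
life-cycle stages (labelled PRE, COMP, POST, ADULT: precompetent larva,
competent larva, postlarva, adult) with **one sequencing library per stage**.
Without biological replicates, the only quantifiable error is technical:
re-counting reads from the same RNA behaves like Poisson sampling, so a count
`N` carries noise on the `√N` scale. All decision rules are built on a
conservative envelope `k·√N` with `k = 5`: between technical replicates the
count difference is expected to stay below `5·√N`, and the relative error
`5·√N / N` becomes negligible at high expression. The envelope is treated as
a bound to verify, not a distribution to sample; replicate simulation is
Poisson by default, with an optional negative-binomial dispersion
(`var = μ + α·μ²`) for robustness checks.

### Depth normalization

Libraries differ only by a per-library scaling factor, so each sample is
multiplied by `total_mapped(reference) / total_mapped(sample)` (reference =
first stage). Rank order and within-sample ratios are untouched. Re-running
the normalization is an error, not a no-op.

### Detection threshold

The threshold is *calibrated*, not assumed: the smallest integer `c` such
that every transcript counted `≥ c` in either of two technical replicates is
seen (`≥ 1` read) in the other. The returned value is exact (no rounding to a
power of two); "detected in the partner" is operationalized as count ≥ 1.
Applied genome-wide, the threshold is quoted on the normalized scale, so a
raw threshold `c` at the lowest-depth library corresponds to
`c × depth_ref / depth_min` after normalization. Detection is inclusive
(`count ≥ threshold` detects).

A calibration caveat, quantified in the test suite: the exact single-pair
threshold is the maximum of the observed discordance distribution — an order
statistic. When the expression distribution has mass at low means (λ roughly
2–12 at the calibrated depth, the very regime that makes a threshold
necessary), a fresh replicate pair exceeds a previously calibrated threshold
with probability of order a few percent, so the exact threshold generalizes
to ~95 % of fresh pairs, not ≥ 99 %. Making it generalize requires a safety
margin above the exact value (e.g. rounding up to a coarse grid); the package
reports the exact value and leaves any margin to the caller.

### Differential expression

All tests run on depth-normalized counts with `y = log2(count + 1)`; the
pseudocount keeps zeros defined and is applied uniformly across tests and
summary statistics.

* **Stage-vs-rest** — for a focal stage, the three other `y` values are a
  sample tested against the focal value with a two-tailed one-sample t-test,
  df = 2 (closed form `p = 1 − |t|/√(t² + 2)`). A gene is up/down only when
  `|y_focal − mean(others)| ≥ log2(fold_cutoff)` *and* `p < α`. Zero-variance
  degenerate inputs collapse to p = 1 (focal equals the common value) or
  p = 0 (flagged).
* **Settlement** — pooled-variance two-sample t-test (2 vs 2 stages, df = 2)
  of the pelagic pair against the benthic pair, same gating.
* **Transitions** — between successive stages, fold is computed on counts
  floored at 1 (so 64 → 256 is exactly four-fold) and the call additionally
  requires `|n₂ − n₁| > k·√max(n₁, n₂)` — the symmetric, conservative
  instantiation of the sampling-error gate. Genes below the detection
  threshold in both stages are excluded rather than reported unchanged.
* **Extreme genes** — `max over stages of [y_focal − mean(y_others)]`,
  flagged at `log2(100) ≈ 6.64`.

Fold cutoffs are inclusive (`≥`), fixed for determinism. The default cutoff
is 4 with a 2-fold permissive variant; cutoff monotonicity (every four-fold
call is a two-fold call) is asserted in the tests. Monte-Carlo
`fold_cutoff_for_false_calling` reconstructs the cutoff-vs-false-calling-rate
curve by simulating replicate pairs at a given mean and taking the
`1 − α` quantile of max/min (zeros floored at 1); at n = 64 it reproduces the
normal-approximation closed form `exp(z_{1−α/2}·√(2/n))` within 0.05.

### Enrichment

Annotations are transferred from the single best similarity hit with e-value
≤ 1e-4 (ties to the lexicographically smaller subject). Term enrichment of a
gene set is scored against the universe of *detected annotated* genes by
drawing `R` same-size sets without replacement (default R = 10,000, seed
mandatory) and using the add-one estimator `p = (b + 1)/(R + 1)`, so p is
floored at `1/(R + 1)` and never exactly zero; BH correction is applied
across tested terms. The engine is vocabulary-agnostic (GO, PANTHER, or any
gene→term table). As R grows the estimate converges to the hypergeometric
upper tail — asserted against scipy's hypergeometric as an independent
oracle, which is never used as the implementation.

Stage enrichment of a gene family uses the **at-peak rule**: a gene counts
toward a stage when its normalized count there is
`≥ min + q·(max − min)` with q = 0.75, on the linear scale by default
(a log-scale variant is available); constant genes are at-peak everywhere
(the inequality is vacuous at zero range) and every gene is at-peak at its
maximum. Fisher's exact test compares family vs non-family at-peak counts,
with both one-sided tails reported; the family is excluded from its own
background by construction of the 2×2 table.

### Read attribution

A read is **exonic** if ≥ 50 % of its aligned length overlaps a gene's exon
union, **intronic** if ≥ 50 % overlaps a gene span without meeting the exon
rule, otherwise **intergenic**; the gene with maximal overlap wins, and the
50 % rule is robust for ~50 nt reads straddling feature edges. Assignment is
strand-agnostic; strand matters only for the sense/antisense orientation of
intergenic reads. Intergenic reads are profiled by the distance from the read
midpoint to the nearest TSS/TTS (ties toward TSS), binned at 1 kb out to
10 kb ("proximal"), beyond which reads are distal; reads on geneless contigs
are distal with undefined orientation and reported separately. Coverage
tracks are bedGraph scaled to reads per 10 million mapped.

### qPCR validation

ΔCt = Ct(target) − Ct(reference gene) per replicate; ΔΔCt differences per
stage against a reference stage; `fold = 2^(−ΔΔCt)`. Folds are invariant
under constant Ct shifts, and changing the reference stage rescales all folds
by one constant. Stage variance is tested per gene with one-way fixed-effects
ANOVA plus all-pairs pooled t-tests, Bonferroni-multiplied and capped at 1.
Concordance with sequencing is reported per gene (Pearson r between log2
qPCR and log2 sequencing fold profiles, both using the +1 pseudocount
convention) and pooled (Spearman between raw Ct and `log2(count + 1)` over
all gene × stage × replicate points; expected strongly negative).

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions end to end: a gene catalogue on
20 contigs (1–5 exons per gene, intergenic gaps of 2–9 kb with ~15 % wide
25–40 kb gaps so distal placements exist), per-stage expected counts
`depth_s · p(g, s)` with Poisson sampling, stage depths proportional to the
emulated libraries and scaled ~400× down (112.5k/82.5k/50k/100k) so the full
pipeline runs in seconds, and four planted gene classes — 50 % constant,
15 % stage-specific, 15 % single-transition step, 20 % silent — with log2
effects uniform on [2, 7] over a log-normal baseline (log2 mean 4, sd 1.5).
64 % of genes are annotated (best hits at e ≤ 1e-4; a fraction of the rest
carry decoy hits above the cutoff); three terms per differential class are
planted at 25× membership odds over a 2 % background — the strength of a
coordinated functional module — and the generator self-check requires their
hypergeometric p < 1e-3. Reads (50,000 by default, 50 nt) are placed exactly
inside exons, introns, or intergenic space per the configured 80.7/5.7/13.6 %
mix, with 90 % of intergenic reads within 10 kb of a boundary and 55 % sense;
the qPCR panel (50 genes × 4 stages × 3 replicates) derives Ct affinely from
log2 expected normalized counts with 0.3-cycle Gaussian noise around a
β-actin-like stable reference.

Not emulated: spliced/junction reads, mapping ambiguity and multi-mappers,
fragment-level (GC, position) biases, library-composition artefacts beyond
per-stage renormalization of relative abundances, symbiont contamination,
and primer-efficiency variation in qPCR. Passing tests therefore demonstrate
the *statistical* machinery under idealized counting noise, not robustness
to alignment or chemistry artefacts in real libraries.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; GFF3 converts at the
  boundary (1-based inclusive), BED is native. Locus deduplication clusters
  transitively overlapping spans per contig *and strand* (opposite-strand
  overlap is not a locus here — the readable alternative is noted in the io
  module) and keeps the longest span, ties to the smaller gene id.
* Single-pass scaling normalization only; no TPM/FPKM/TMM-style competitors,
  which require assumptions a replicate-free design cannot check.
* Every stochastic component takes an explicit seed; the pipeline fans one
  top-level seed out through `SeedSequence.spawn` in a fixed order (synthetic
  data, calibration, enrichment), and two runs of the same config are
  byte-identical.
* At desk scale the acceptance checks use: 10,000 genes for null error
  control, 100,000 replicate pairs for the envelope and fold-cutoff checks,
  R = 10,000–20,000 resamples for enrichment, and 1,000 trials for
  calibration generalization.

## Known limitations

* The 5√N envelope is calibrated for the detection regime. For Poisson noise
  the bound sits at `5/√2 ≈ 3.5` standard deviations of a count difference,
  so at deep coverage (λ ≳ 10³) violations occur at a few × 10⁻⁴ per gene —
  the envelope stops being conservative. The conservatism check is therefore
  run over the detection-regime count distribution (means ≥ 16, log-normal),
  where the discreteness of low counts keeps the bound > 4σ effective.
* The exact replicate-concordance threshold generalizes at ~95 %, not ≥ 99 %,
  for the reason quantified under *Detection threshold* above.
* With df = 2 the stage-vs-rest t-test has little power near the fold cutoff;
  sensitivity on the full generator (effects down to 4-fold, baselines down
  to the detection floor) is ~0.5 by design, while the controlled recovery
  experiment (8-fold at baseline ≥ 256) reaches ≥ 0.9 with correct direction.
* Enrichment p-values are resolution-limited at `1/(R + 1)`; ranks among
  floor-tied terms are broken by observed overlap and term id.
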