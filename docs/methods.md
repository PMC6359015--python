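# Methods

## Design and model

The package analyzes a complete 2×2 factorial transcriptomics design:
genotype ∈ {WT, KO} crossed with environment ∈ {ground, flight}, with at
least two biological replicates in every cell (the defaults emulate an
unbalanced 5/5/3/3 layout — five wild-type and three knockout replicates
per environment). All modeling is on log2 intensities.

Each gene is fit with a **cell-means parameterization**: four group means
and one pooled residual variance s²_g on d_g = N − 4 degrees of freedom.
Contrasts are therefore literal group-mean differences, and the reported
log2FC reads directly as "first-named group minus second". The residual
variance is pooled across all four cells (homoscedastic within gene),
matching a single linear-model fit over all samples rather than four
separate two-group fits; the simulator makes the same assumption.

**Variance moderation.** Gene-wise variances are modeled as exchangeable
draws from a scaled inverse chi-square prior, σ²_g ~ d₀·s₀²/χ²_{d₀}.
Marginally s²_g/s₀² is then an F variate, so with z_g = log s²_g:

- E[z] = log s₀² + ψ(d_g/2) − log(d_g/2) − ψ(d₀/2) + log(d₀/2)
- Var[z] = ψ′(d_g/2) + ψ′(d₀/2)

d₀ is obtained by inverting the trigamma function on Var[z] − ψ′(d_g/2)
and s₀² from the mean equation. The trigamma inversion uses bracketed
Brent root-finding on [1e−8, 1e8] with xtol 1e−12. When the observed
dispersion of z does not exceed the ψ′(d_g/2) floor, or the fitted d₀
exceeds 1e6, d₀ is reported as infinite: every posterior variance equals
s₀² and the t reference becomes normal. A consequence worth knowing: in
the degenerate case where all s²_g are exactly equal, the log-moment
estimator returns s₀² = s²·exp(log(d_g/2) − ψ(d_g/2)) — the common value
times a chi-square bias factor that tends to 1 as d_g grows (≈1.09 at
d_g = 12). Genes with s²_g = 0 are excluded from the moment fit (their log
is undefined) but are still shrunk by the posterior formula.

The moderated statistic is t̃ = Δ/√(s̃²(1/n₁+1/n₂)) with
s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g), two-sided p from t on d_g + d₀ df.
Setting d₀ = 0 disables moderation exactly: the test collapses to an
ordinary pooled two-sample t-test (pooling the four-cell residual), which
the test suite verifies to 1e−10 against an independently coded oracle.

**Multiplicity.** BH step-up adjustment is applied per comparison (across
genes), delegated to `statsmodels.stats.multitest` and verified against a
hand-coded step-up oracle.

**DE calls.** A gene is significant in a comparison iff p < 0.01 and
|log2FC| > 1, both strict inequalities. The p-value gated is BH-adjusted by
default with a switch to raw p: published analyses of this design are
often ambiguous about which was thresholded, so both are first-class and
the choice is recorded in the run log.

## Classification taxonomy

The four statuses per gene are ordered (WT vertical, KO vertical, ground
horizontal, flight horizontal). Categories are defined purely on this
4-tuple; no effect-size or direction constraint is imposed beyond the
significance pattern (a corrected gene may move up or down to reach the
WT level). "The genotypes match in flight" is operationalized as
non-significance of the flight horizontal comparison at the global
thresholds — the only operational reading of "similar expression level"
consistent with applying one set of gates throughout.

The named categories are not exhaustive over the 81 possible patterns, so
a strict precedence order (shared > required/corrected >
genotype-dependent/compensated > persistent > other) plus `other_pattern`
and `none` buckets makes classification total and deterministic. Most
precedence pairs are vacuous — the criteria are already disjoint (e.g.
required demands a non-significant KO vertical, which excludes both shared
categories; required and genotype-dependent disagree on the ground
horizontal) — and the test suite proves disjointness by scanning all 81
patterns against literal transcriptions of the criteria. Precedence only
bites where a pattern genuinely satisfies two lists (e.g. a shared pattern
that also shows a persistent genotype difference).

## Synthetic data

The generator emulates summarized log2 microarray intensities:

- baseline per gene ~ N(7, 1.5²) log2 units (typical of summarized array
  data spanning roughly 2–14);
- per-gene true variance from the same scaled inverse chi-square prior the
  test assumes, default d₀ = 4, s₀² = 0.05 (per-replicate sd ≈ 0.22 log2
  units, i.e. well-behaved probes with occasional noisy ones from the
  heavy lower-χ² tail);
- i.i.d. Gaussian noise on the log2 scale, one shared variance per gene
  across all four cells;
- planted effects of 2 log2 units by default (4-fold, comfortably above
  the |log2FC| > 1 gate), arranged per category so that the noiseless
  pattern satisfies exactly that category's criteria; 20 genes per
  category by default, remainder null.

Three planted effects are free per gene (ground genotype difference, and
the environment response of each genotype); the flight genotype difference
is their linear combination and is recorded in the truth table for
convenience. All randomness flows from a single `numpy` Generator seeded
with one integer, so identical configs are bit-reproducible.

What the simulator does **not** emulate: probe-level effects and
summarization artifacts, detection-call error, batch/spatial effects,
mean–variance dependence, correlated genes, and non-Gaussian noise.
Passing recovery tests therefore demonstrate the statistical machinery is
correct under its own assumptions, not that real arrays satisfy those
assumptions.

## Ingest and normalization

The pipeline starts from a summarized expression TSV; probe-level
processing is out of scope. Because upstream processing chains vary (and
are sometimes reported inconsistently), log2 transformation and quantile
normalization are optional, independently skippable steps — a matrix that
is already normalized on the log2 scale can be ingested as-is
(`input_scale="log2"`, `quantile=False`).

Quantile normalization maps each sample's order statistics onto the
across-sample mean of order statistics; ties receive the mean of the
target quantiles they span (midrank convention). With tie-free columns the
post-normalization sorted columns are identical to machine precision; with
ties the identity is only approximate at the tied ranks, which is why the
property test restricts to tie-free inputs and ties get their own test.

Undetected-gene filtering drops genes whose detection call is absent in
every sample; without a call table, an optional intensity floor on the
per-gene maximum is the fallback, and no filtering is the default.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), computed by `scipy.stats.hypergeom` and
verified against exact rational-arithmetic summation. Terms mapping fewer
than 5 background genes (configurable) are excluded before testing. No
multiplicity adjustment by default, matching singular-enrichment-analysis
convention; a BH switch is available. The default background is the
post-filter gene universe of the run. GO-graph propagation and slim
rollups are out of scope — the annotation is whatever GMT-style file the
user supplies.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated data at
desk scale: 10,000 genes for calibration checks (type-I error within 3
binomial standard errors of 0.01; prior recovery within 20%/10% for
d₀/s₀²), 1,000 genes × 20 (tests) or 10 (script) seeds for planted-category
recovery at a 4 log2-unit effect, and 1,000 genes for the
ordinary-t equivalence check. These sizes give Monte-Carlo error well
inside each tolerance while keeping a full run under a few seconds.

Degenerate inputs are handled explicitly: zero-variance genes give t = ±∞
(p = 0) when the contrast is nonzero and t = 0 (p = 1) when it is zero;
all-zero-variance matrices are rejected at moderation; empty gene sets
classify to empty tables with zero counts.

## Known limitations

- The classifier consumes only the status 4-tuple; borderline genes whose
  true pattern straddles a gate land in `other_pattern` or a neighboring
  category, so category counts are threshold-sensitive (as in any
  set-logic analysis of this kind).
- Moderation assumes a single prior across all genes; no robust/windowed
  variant or intensity-dependent trend is implemented.
- The four comparisons are fixed; arbitrary contrast matrices are not.
- Enrichment treats genes exchangeably (no gene-length or expression bias
  correction).
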