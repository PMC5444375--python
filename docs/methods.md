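# Methods

## Model

varpath treats a pathway as a draw from a multinomial distribution over
discrete variability levels. Each measured gene g receives a dispersion
statistic s(g) from the samples of one phenotype, genes are partitioned
into m ordered levels by fixed numeric boundaries on s, and a pathway with
n measured genes yields a count vector (O₁,…,O_m), ΣOᵢ = n.

Two null hypotheses are available:

* **One-group**: (O₁,…,O_m) ~ Multi(n, p), where pᵢ is the proportion of
  *all* measured, level-assigned genes in level i (the reference
  distribution). The reference deliberately includes the pathway's own
  genes — it is the marginal composition of the transcriptome, and no
  leave-one-out correction is applied. For pathways that are a small
  fraction of the universe this bias is negligible; for a pathway
  approaching the size of the universe the test degenerates (its counts
  converge to the reference), which is the expected behavior, not an error.
* **Two-group**: the two phenotypes' count vectors share one underlying
  level distribution. Tested by the homogeneity chi-squared on the 2×m
  table with expected counts from pooled proportions and m−1 degrees of
  freedom; levels empty in both groups are dropped and the df reduced. An
  exact variant tests group 1's counts against group 2's proportions
  (0.5 added to every group-2 level when any is zero, to avoid a
  zero-probability null); it is asymmetric in the group roles and labeled
  as such, whereas the homogeneity chi-squared is exactly symmetric.

The package assumes the input matrix is already normalized; no transform
(log or otherwise) is applied internally, and whether variability is
assessed on the log or linear scale is the user's choice, made upstream.
Missing values are rejected rather than pairwise-deleted so the n in the
SD denominator is unambiguous.

## Estimators

SD (n−1 denominator), CV = SD/mean, MAD (unscaled median absolute
deviation), plus MEAN for running the identical machinery on average
expression. CV is undefined for genes with mean ≤ 0: near-zero averages
produce arbitrarily large CVs that reflect the denominator, not
dispersion. Such genes are flagged, counted in the run log, and excluded
from discretization — never silently dropped. The
`mean_variability_correlation` diagnostic (Pearson r between the per-gene
mean and the statistic) supports choosing the estimator least coupled to
average expression; a constant mean vector makes the correlation
undefined and it is reported as NaN rather than coerced to zero.

## Discretization

**One-group (mixture) mode.** 1-D Gaussian mixtures with G = 1..4
components (user-overridable maximum) are fitted under both an
equal-variance and a per-component-variance model; the (G, model) pair
with the best BIC wins. Four levels is the default ceiling because a
handful of ordered labels (low/medium/high/very high) stays
interpretable. EM numerical choices: k-means++ initialization, 3
restarts, convergence tolerance 1e-5 on the lower bound, 300 iteration
cap, 1e-8 variance floor against component collapse, all driven by one
seed. Three seeded restarts with k-means++ are ample for univariate
mixtures — in benchmarking they reproduced the selections of a 10-restart
/ 1e-6 / 500-iteration configuration while being an order of magnitude
faster. Components are ordered by mean; empty components (possible when
posteriors concentrate) are removed and levels renumbered.

Cluster assignments are converted to *fixed boundaries*: the cut between
adjacent levels is the midpoint between the largest value assigned to the
lower component and the smallest assigned to the upper. Assignment then
goes through the boundaries, not the raw posteriors, which guarantees
monotonicity (a larger statistic never gets a lower level) and makes
re-assignment idempotent and portable (the scheme serializes to a small
TSV). Interleaved clusters (non-monotone boundaries) abort with an error
rather than silently producing a non-ordinal scheme.

**Two-group (percentile) mode.** m is fixed at 3; boundaries are the 33rd
and 66th percentiles of the pooled per-group statistic values (two values
per gene), computed by linear interpolation between order statistics (the
common "type 7" rule — no rule is canonical and this is the numpy
default). The boundary convention everywhere is closed below / open
above: a value equal to a cut belongs to the lower level, so the low level
is exactly "0 through the 33rd percentile". Heavy ties can collapse the
two percentiles; the scheme then keeps m = 3 with empty upper levels, and
empty levels are merged before testing (see below).

## Testing

**Exact multinomial test.** The p-value sums Multi(n, p) probabilities of
all C(n+m−1, m−1) outcome vectors whose probability does not exceed the
observed outcome's. All work is in log space; an outcome within a 1e-9
relative tolerance of the observed probability counts as a tie and is
included, so the observed outcome always contributes and p > 0. The
enumeration is capped (default 2,000,000 compositions); above the cap the
caller falls back to the chi-squared test (default) or a Monte-Carlo
version with p = (1 + #{sims no more probable}) / (reps + 1), and the run
log records every fallback. Repeated testing against one (n, p) reuses a
pre-sorted outcome table (`ExactMultinomialNull`), making 5,000-replicate
calibration runs cheap.

**Chi-squared test.** X² = Σ(Oᵢ−Eᵢ)²/Eᵢ with Eᵢ = n·pᵢ and m−1 df.
Levels with reference probability 0 are merged into the nearest adjacent
level (lower preferred) before testing — with the merged level's counts
added — and noted in the result row.

**Localization.** Per level, a two-sided exact binomial test compares Oᵢ
with n·pᵢ (one-group) or with group 2's proportion (two-group,
pseudocount-guarded). Two-sidedness doubles the smaller tail and caps at
1 — simple, conservative and platform-stable; direction is "up" at or
above the expectation. Per-level p-values are reported unadjusted with a
significance flag at α (default 0.05); the pathway-level p-values are BH
adjusted across all tested pathways of the run.

## Power harness

Effect size is Cohen's w = √(Σ(qᵢ−pᵢ)²/pᵢ), chosen because it is the
standard chi-squared goodness-of-fit effect size and gives the analytic
noncentral-χ² power approximation (ncp = n·w², df = m−1) as an
independent oracle; simulated chi-squared power matches it within
Monte-Carlo error for pathways of ≥ 100 genes. The shape-contrast
routine compares perturbations of identical w but different shape
(skewed vs symmetric); skewed deviations concentrate the same w in fewer
cells and are detected with more power. The estimator-comparison routine
generates full expression matrices, so sample size acts through
estimator noise as it does in real data; it reports planted-level
recovery (adjusted Rand) and planted-pathway power per estimator. All
randomness descends from one top-level seed through numpy's
`default_rng([seed, k])` spawning, so every grid point is independently
reproducible.

## Synthetic data

The generator emulates the data structure the method assumes: each gene
draws a latent level, then a mean (Uniform over the level's mean range)
and a sampling SD (Uniform over the level's SD range), then i.i.d.
Normal(mean, SD²) values per sample. Defaults: 5,000 genes — a
transcriptome-scale universe, so a planted pathway of ~100 genes remains
a small fraction of the reference — 20 samples per group, three levels in
equal proportion with SD ranges 0.25–0.35, 0.9–1.1 and 2.8–3.2
(well-separated relative to the sampling noise of an SD estimate from 20
samples, whose CV is ≈ 1/√(2(n−1)) ≈ 16%). The level fractions double as
the background reference probabilities. Planted pathways draw member
levels from a perturbed vector q (optionally group-specific in two-group
designs; background genes keep one latent level across groups); five
size-matched decoy sets per planted pathway are drawn from background
genes to give empirical-FDR estimates a stable denominator. A log-normal
noise option produces skewed, mean-coupled values for CV stress-testing.

What the generator does *not* emulate: gene–gene correlation, count
discreteness, zero inflation/dropout, batch effects, and
mean–variance coupling beyond the log-normal option. Passing tests
therefore certify the statistical machinery under its own assumptions —
independence across genes and a latent level structure — not robustness
to platform artifacts, which must be handled by upstream normalization.

## Problem sizes and numerical notes

Default validation batteries: type-I calibration at n = 30 genes /
3 levels (one-group) and 100 genes per group (two-group) with 5,000
replicates; power grids over 50–400 genes at 4,000–5,000 replicates;
mixture recovery at 400 points / 50 seeds and 500 points / 100 seeds;
planted-pathway battery of 100 end-to-end runs with the exact test. At
these sizes the discrete exact test's achievable type-I error at α = 0.05
is ≈ 0.047 (exactly computable from the null table); at much smaller n
the test is valid but conservative, as discrete exact tests are.

Chi-squared and exact p-values agree closely where decisions are made
(differences well under 0.02 for p ≲ 0.35 at n ≥ 200 in our batteries)
but can differ by ~0.03 in the clearly-non-significant mid-range, because
the two tests order outcomes differently (by probability vs by X²); this
is a property of the tests, not a numerical issue.

Degenerate inputs: an all-constant statistic vector yields one level; a
pathway whose counts collapse to a single non-empty comparable level is
reported untested (`test_used = none`) rather than given a vacuous
p-value; BH leaves NaN p-values out of the adjustment.
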