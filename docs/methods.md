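# Methods

This note documents the models behind each component, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Focal-junction quantification and testing

A spliced isoform that differs from its unspliced form by a short excised
intron (XBP1s: 26 nt removed at chr22:28,796,122–28,796,147, hg38, '+'
strand) is visible in RNA-seq only through reads spanning that junction.
Per sample, relative abundance is the focal junction's unique spliced reads
per million total unique spliced reads in the same `SJ.out.tab` table.
Multi-mapping junction reads (STAR column 8) are carried through I/O but
never counted: uniqueness avoids double-counting, and the aligner's
multi-mapper allocation is not reproducible downstream.

Differential usage fits the focal counts with an NB2 GLM (log link):
intercept, treatment indicator, and a library covariate. The library
covariate is the total unique spliced reads of the same table — the only
depth measure available from junction data alone — entered as log₁₀ so that
it acts as an approximate offset (a coefficient of ln 10 would be an exact
offset); a `library_scale="raw"` switch uses the untransformed total. The
covariate is mean-centred for conditioning; slopes are unaffected. The
treatment effect is reported on the natural-log scale with a two-sided Wald
test.

The focal junction is matched by exact coordinates, no tolerance; a
junction recorded with unknown strand (STAR code 0) matches either query
strand. A focal junction absent from a table counts zero.

## NB GLM engine

One vectorised fitting routine serves both the junction test and
differential expression: IRLS for the coefficients at fixed dispersion,
alternating with per-gene dispersion estimation, until the coefficient
change is below 1e-8 (at most 100 IRLS iterations; non-convergent fits are
flagged and excluded from downstream multiplicity correction). Fitted means
are clamped to exp(±30) to avoid overflow on degenerate data.

Dispersion (α in var = μ + αμ²) maximises the Cox–Reid adjusted profile
likelihood — the NB log-likelihood at the current fitted means minus half
the log-determinant of the weighted information X′WX — evaluated on a
41-point log-spaced grid over [1e-8, 100] and refined by a parabola in
log α around the grid maximum. The CR adjustment is the REML analogue for
GLMs and removes the leading small-sample downward bias of plain ML
dispersion; plain ML and a method-of-moments estimator remain available
(`dispersion="ml" | "moment"`). Fixing α = 0 reproduces a Poisson GLM
(verified against statsmodels to 1e-4).

Wald standard errors come from the expected information at the fitted
dispersion, i.e. the dispersion is treated as known in the coefficient
covariance, the same convention as R's `glm.nb`. The Wald statistic is
referred to a Student t with residual degrees of freedom (samples minus
coefficients) rather than a normal: the dispersion entering the SE is
estimated from those same few residual degrees of freedom, and in null
simulations at the triplicate scale of this design the normal reference
rejects at roughly twice the nominal 5% while the t(n−p) reference is close
to nominal (measured ≈4% at α = 0.05). For larger designs t(n−p) converges
to the normal, so nothing is lost at scale.

## Differential expression

Filtering keeps a gene only if *each* of the two groups contains at least
one sample with strictly more than five counts; a flag switches to the
weaker any-sample-overall reading. Size factors are classical
median-of-ratios: per-gene geometric means over samples (genes containing
any zero excluded), per-sample medians of count/geomean, then rescaled to
geometric mean one so the factors are a pure relative-depth measure. When
no gene is positive everywhere, `pseudo_reference=True` computes geometric
means over the non-zero entries of genes positive in at least half the
samples.

Each gene's model is intercept + group with offset log(size factor);
log₂FC is the group coefficient divided by ln 2, with no pseudo-count (the
GLM needs none). p-values are BH-adjusted over the converged genes only.
Dispersion is strictly per-gene — no trend, no shrinkage, no outlier
replacement, no independent filtering. Consequences worth knowing: at
triplicate scale the test has modest single-gene power (a simulated
two-fold change rarely clears a 5% FDR), so cross-perturbation comparisons
here lean on rank-based statistics (top-n overlap), which remain well
powered; and results will not numerically match shrinkage-based tools.

Top-n selection orders one direction's genes by ascending p, breaking ties
by |log₂FC| descending and then gene id, and warns when fewer than n genes
qualify.

## Overlap and enrichment statistics

The top-n overlap test treats one list as fixed and asks how many of the
other list's n genes land in it if they were an arbitrary n-subset of the
universe: k ~ Binomial(n, n/universe) under the null, with the exact upper
tail computed by log-space term summation (verified against exact rational
arithmetic to 1e-12). The universe — the number of genes that entered
differential testing — is a required explicit argument; the pipeline's
`"intersection"` setting uses genes passing the filter in both contrasts.
The binomial model ignores the weak negative dependence between overlap
indicators (sampling without replacement), making it very slightly
conservative for small n/universe.

Set-level enrichment compares the log₂ fold-change distribution of a set's
tested members against all other tested genes with a two-sided two-sample
KS test (asymptotic p). Sidedness is not assumed; a direction (sign of the
member median minus non-member median) is reported separately so
activated/repressed calls remain possible. Sets with fewer than
`min_set_size` (default 15, hallmark-scale) tested members are skipped with
a warning. A Fisher's-exact variant tests over-representation of a selected
gene list (default selection: adjusted p < 0.05 and a fold-change sign
filter, both configurable) one-sided against the hypergeometric null; both
tests are provided because distribution-shift and selection-based
enrichment answer slightly different questions, and neither is assumed to
be "the" analysis.

## Signatures and survival

Quantile normalisation forces every sample (column) onto the mean empirical
distribution: each column's sorted values are replaced by per-rank means
across columns; ties receive the mean of the reference values their rank
span covers, which preserves idempotence. It removes cohort-level
distributional effects and, deliberately, any sample-level distributional
signal.

A signature score is the mean of per-gene z-scores (centred and scaled
across samples, sample SD): the simplest score that is comparable across
cohorts after quantile normalisation, invariant to gene order and to
per-gene location/scale. Absent genes are logged; zero-variance genes are
dropped with a warning. Scoring is per-cohort; cohorts are never pooled
before scoring. Stratification splits at the cohort median score with ties
going to the low group. Stratified expression comparisons use Welch's
t-test; genes constant in both strata are reported as degenerate with
p = 1 rather than an error, so one flat gene cannot abort a panel.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(events processed before censorings at tied times, the standard
convention); the package re-derives the survival steps, at-risk counts and
the 1-df chi-square through its own result types, and the test suite checks
them against hand-enumerated product-limit and hypergeometric
expectation/variance tables and against label-permutation nulls. Survival
endpoint semantics (disease-free vs biochemical-recurrence-free) are
metadata only; the statistics are endpoint-agnostic.

## Synergy criterion

The default ("literal") reference for a combination is Fa·(1−Fb), implemented
literally as stated by its source, with strict inequality Fc > Fa·(1−Fb)
for a synergy call and the margin Fc − threshold reported for ranking.
Classic Bliss independence (Fa + Fb − Fa·Fb) is exposed as `mode="bliss"`
rather than silently substituted. Note the two references coincide only
when responses are read on complementary scales: if "fractional response"
means fraction *surviving*, Fa·Fb would be the Bliss survival reference and
Fa·(1−Fb) is something else again. Because the source does not define the
scale, the criterion is applied as printed and the ambiguity is flagged
here; which combinations qualify can change with the interpretation.

## Synthetic-data generator

The generator emulates the *structure* of the study — not its biology — at
a desk scale chosen to keep full runs in seconds-to-minutes: 10,000 genes,
3 samples per group (the triplicate RNA-seq design), ~5×10⁶ unique spliced
reads per sample, NB dispersion 0.1 for gene counts and 0.05 for the focal
junction, log-normal baseline means (ln-scale mean 4, SD 1.5, i.e. median
~55 counts), 10% DE genes of which 30% form a core down-regulated in both
contrasts (magnitudes |N(1, 0.5)|), remaining DE effects N(0, 1) with
magnitudes below 0.25 pushed to ±0.25 so "DE" is never vacuous, ±10%
log-normal depth jitter, survival cohorts of 300 with exponential hazards
(baseline 0.1, default log hazard ratio ln 3 per latent-score SD, 30%
censoring via an independent exponential calibrated to that marginal rate),
and 100 drug combinations with interaction +0.1 and response noise SD 0.05.

One root seed expands to fixed per-component streams
(`numpy.random.default_rng([seed, k])`, k = 1…4 for counts, junctions,
survival, combos), so components regenerate independently and every output
is byte-reproducible.

What it does not emulate — and hence what passing tests do not show about
real data: genomic feature structure (gene lengths, GC, mappability),
correlated genes and batch effects, cohort-specific platform differences,
isoform-level competition between the spliced and unspliced junction
(only the spliced junction is generated), informative censoring, and
dose–response curvature. Tests passing on this generator demonstrate that
the statistics are implemented correctly and calibrated under their own
model assumptions, not that those assumptions hold in any particular
dataset.

## Numerical choices and degenerate inputs

- Binomial tails by `logsumexp` over log terms; exact for k ≤ n, 1 for
  k ≤ 0.
- p-values clamped into (0, 1] before −log₁₀ reporting.
- All-zero focal counts, empty junction tables queried for a ratio,
  cohorts without events, constant score vectors, and universes smaller
  than the list length raise typed errors rather than returning NaN.
- Quadrant concordance excludes genes with a zero fold change in either
  contrast; Pearson r within the jointly-down quadrant is NaN below three
  genes.
- Gene labels are case-sensitive exact strings throughout; no alias
  mapping.

## Known limitations

- The junction test models one focal junction; it is not a genome-wide
  differential-splicing method and does not compute percent-spliced-in.
- Without dispersion shrinkage the DE test is conservative and low-powered
  at n = 3 per group; it is meant for rank-based downstream comparisons,
  not for maximising single-gene discoveries.
- The KS enrichment p-value is asymptotic; for sets of ~15 members it is
  mildly conservative (the permutation comparison in the test suite bounds
  the discrepancy).
- The five-gene prognostic signature is consumed as given; the
  feature-selection procedure that produced it is out of scope.
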