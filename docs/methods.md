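# Methods

This note documents the models, priors, numerical choices and known
limitations of `dhpredict`. It is the design record for maintainers; the
README covers usage.

## Study design being emulated

The package targets the analysis of a biparental maize doubled-haploid (DH)
panel and its haploid progenitors: ~187 lines genotyped at ~1.3k SNPs on 10
chromosomes, phenotyped for many traits in multiple environments under a
randomized complete block design with two replications. Two trait classes
matter for the trait-assisted prediction question: "agronomic-like" traits
that are cheap to measure on every line (moderate heritability) and
"stalk-quality-like" traits that are expensive to measure (lower
heritability). A bundled reference table (`dhpredict.data`) carries
published per-trait heritabilities and DH-haploid correlations from such a
panel (Zheng58 x Chang7-2) in environments BJ2014 and SJZ2014; it is used
for worked examples and as the scale reference for simulator defaults.

## Synthetic populations (`simpop`)

Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson(L/100) for map length L in cM, positions uniform on the genetic
map, no interference. The map function is a modeling choice — the block
structure of DH genomes (few, long parental segments) does not depend on
interference at this marker density. Parents are fully informative
(opposite homozygotes at every marker), so the F1 is heterozygous
everywhere and parental origin is read directly off each gamete.

A DH line is one gamete doubled (dosages 0/2 only). A configurable
minority of lines (default fraction 0.1) samples its gamete after extra
generations of selfing (default 3), reproducing the long right tail of
recombination counts seen when some lines descend from advanced selfing
generations. Haploid lines carry marker-for-marker the gamete of their DH
line: a homozygote has a single gamete type and the inducer genome is
eliminated, so genotypic identity is the genetically forced assumption.

Phenotypes follow `y = Xb + Zu + e` with `vec(U) ~ N(0, G0 (x) K)` over a
compound trait dimension (trait x environment x population) and plot
residual vectors iid `N(0, R0)`. DH-vs-haploid expression differences are
modeled purely through the between-population blocks of `G0` (a genetic
correlation < 1 between the DH and haploid version of a trait), not
mechanistically. Block effects are fixed, drawn once per
(population, environment, block) from `N(0, 0.25^2)`. All randomness flows
from a single seed through named substreams (`dhpredict._rng.substream`),
so each module's draws are reproducible independently of call order.

What the generator does *not* emulate: genotyping error, segregation
distortion, marker ascertainment, selection during DH production,
spatial field trends, and genotype-by-environment structure beyond what
the user encodes in `G0`. Passing tests therefore demonstrate correctness
of the estimators under the stated generative model, not robustness to
those real-data artifacts.

## Marker QC and relationships (`markers`)

QC applies strict thresholds (boundary values fail): MAF > 0.05, marker
missing rate < 0.20, marker heterozygosity < 0.10, then line missing rate
< 0.20 and line heterozygosity < 0.20. Markers are filtered before lines
in a single pass; the order is configurable in principle and stated in the
QC report because it affects the result. The GRM is VanRaden method 1 with
per-marker mean imputation of missing dosages. On a fully homozygous
biparental DH panel with allele frequencies near 0.5 the diagonal is ~2 —
the expected inbreeding inflation — so downstream simulations that want
unit-scale genetic variance use `K / mean(diag(K))`.

Recombination counting operates on parental-origin codes: a switch between
consecutive non-missing informative markers counts as one event; missing
cells are skipped, never counted. This undercounts double crossovers
between adjacent markers, which is negligible at ~0.4-1 cM marker spacing.

## Univariate models (`lmm`)

REML throughout, restricted likelihood profiled over the variance ratio
after one eigendecomposition of the covariance structure
(`H = Z K Z'`). The 1-D optimization uses a 41-point coarse grid on
log-ratio in [-12, 12] followed by bounded Brent refinement to an xatol of
1e-9 on the log scale; a ratio below 2e-5 collapses to the sigma2_g = 0
boundary. Unphenotyped lines receive breeding values through the
cross-block of K (conditional mean).

BayesB is a Gibbs sampler over a spike/slab mixture: effect exactly zero
with probability pi (default 0.95), otherwise normal with marker-specific
variance under a scaled-inverse-chi-square(df = 5) hyperprior whose scale
solves prior genetic variance = r2 * var(y) (default r2 = 0.5). The
inclusion indicator is updated with the effect integrated out (marginal
Bayes factor), so no Metropolis step is needed. Default chain lengths are
burn-in 5,000 / 20,000 iterations; tests use shorter chains (300-1,200)
because the toy problems mix in tens of sweeps. The kernel is compiled
with numba.

## Multi-trait models (`multitrait`)

`fit_multitrait` implements the t-trait animal model with selectable
covariance structures (genetic D / UN / FA(k); residual D / UN) by Gibbs
sampling. Computation: the line dimension is diagonalized once by the
eigendecomposition of K (eigenvalues floored at 1e-8); each sweep the
trait dimension is diagonalized by a generalized eigendecomposition of
(G0, R0), making the genetic-effect update an elementwise n x t draw.
Inverse-Wishart draws use a Bartlett construction (validated against
scipy's moments) because sampler-call overhead dominates short chains.

Priors: inverse-Wishart(t + 2, 0.5 * diag(var(Y))) for UN blocks;
scaled-inverse-chi-square(df = 5) with prior mean half the trait variance
for D variances; flat on the intercept (the only fixed effect — the
designs modeled here have no other line-level covariates). For FA genetic
structure the loadings get N(0, 1) priors and the idiosyncratic genetic
variances a scaled-inv-chi2 with prior mean 0.1 * var(Y): the factors are
expected to absorb shared genetic structure, and a larger scale
systematically under-attributes it (rank-1 recovery degrades from ~0.93
to ~0.65).

Missing and cross-validation-masked cells are sampled from their
row-conditional normal each sweep (patterns grouped for vectorization), so
held-out prediction is the posterior mean of `1 b' + U` at masked cells —
prediction is a by-product of fitting, and `predict_masked` refits if
asked for a cell that was observed during fitting. Thinning keeps every
5th post-burn-in draw by default.

Posterior shrinkage of genetic correlations is real and worth knowing
about: with one plot-equivalent observation per line and h2 ~ 0.4, the
posterior mean of rG sits well below a strong generating value (e.g. ~0.5
for truth 0.71). This is not an implementation defect — an independent
REML route (variance components of sum and difference traits) shows the
same attenuation and realized-value checks confirm the generating
correlations — it is the price of weak per-line information in a single
biparental family. Fitting on line means of two replicate blocks (the
emulated field design) roughly halves the residual variance and brings
median recovery error under 0.1; all recovery checks therefore generate
plot-level data with two blocks and fit on line means.

`fit_factor_model` is the high-dimensional sampler for many traits:
`Y = 1 mu' + F Lambda' + Ug + E`, k factors (default 8) whose scores split
into K-correlated and iid parts via a per-factor genetic fraction sampled
on the grid {0, 0.1, ..., 0.9, 0.99}; a trait-specific genetic term Ug
(diagonal structure); diagonal residual. Loadings carry a
multiplicative-gamma column shrinkage prior (local gamma(3/2) precisions,
column multipliers gamma(2, 1) then gamma(3, 1)), so later columns are
progressively shrunk and k is an upper bound on effective rank. This is a
deliberately simplified factor-analytic model in the MegaLMM tradition —
same covariance decomposition and CV2 prediction mechanism, simpler
priors — and claims qualitative, not bit-level, agreement with that
package.

## Correlations and selection theory (`gencor`, `selection_theory`)

Genetic and phenotypic correlations are plug-in ratios of posterior-mean
variance components, clipped to [-1, 1] (Monte-Carlo noise can breach the
bound); the residual DH-haploid covariance is fixed at zero because the
two populations are planted in separate randomized blocks. Heritability is
sigma2_G / (sigma2_G + sigma2_e) on the scale of the fitted data.
Comparing plug-in vs posterior-mean-of-ratio showed differences < 0.01, so
the simpler plug-in is the default.

Selection responses are the standard breeder's-equation forms: direct
`R = i h sigma_A` and indirect `R = i r_A h sigma_A`, with relative
efficiency `r_A h_H / h_D` at equal intensities; a truncation-selection
helper converts a selected fraction to intensity via the normal hazard.

## Cross-validation and accuracy (`crossval`, `scenarios`)

CV2 plans mask cells, not lines: in the single-environment scheme a random
half of lines loses all focal-trait cells (secondary traits stay fully
observed); in the multi-environment scheme an independent 20% of lines is
masked per environment. The same plan object is reused across models so
every model sees identical training data.

Two accuracy estimators:

* `accuracy_cor_y` — Pearson cor(y, a_hat) over masked cells; used for
  multi-environment scenarios, where held-out phenotypes come from
  different plots than the training data.
* `accuracy_genetic` — cor_g(a_hat, y) * sqrt(h2_a_hat), the correlation
  between prediction and true breeding value; used in the
  single-environment trait-assisted setting, where focal and secondary
  traits share plots and plain Pearson correlation is inflated by shared
  plot effects. Implemented by a short-chain bivariate UN-UN fit of the
  standardized (a_hat, y) pair on the test lines. A faster REML
  sum/difference route exists (`method="sumdiff"`) but saturates at the
  clip boundary on ~75-line biparental test sets and cannot discriminate
  models, so it is not the default. Like every genetic-correlation
  estimator at this scale, the default carries shrinkage and noise
  (SD ~ 0.15-0.2); model comparisons pair the Monte-Carlo seed across
  models within a repeat so much of the noise cancels in differences.

The corrected resampled t-test inflates the paired-t variance by
(1/J + n_test/n_train) to account for overlapping training sets across
repeats: rho = 1.0 for the 50:50 scheme and 0.25 for 80:20. No
multiple-testing correction is applied across traits by default
(per-trait tests are reported individually); a Benjamini-Hochberg pass is
a one-liner on the returned p-value column if wanted.

`scenarios.trait_assisted_scenario` builds the headline comparison: 8
secondary traits (h2 in [0.3, 0.6]) and 12 focal traits (h2 in
[0.15, 0.4]) on 150 DH lines, genetically connected by a two-factor
structure calibrated so secondary-focal genetic correlations fall in
[0.4, 0.8]; optionally every trait gets a haploid counterpart at
DH-haploid genetic correlation 0.7 (the reference-table median). The
trait counts are a scaled-down rendition of the study's 17 + 18 traits,
chosen so the full J = 20-repeat comparison (factor model vs per-trait
GBLUP, genetic accuracy metric) runs in minutes; the qualitative contrast
(clear multi-trait gain, null haploid contribution) is insensitive to the
exact counts.

`scenarios.ttest_calibration` measures type-I error on 500 null studies
(60 samples, two exchangeable predictors, J = 10 overlapping 50:50
splits): the corrected test rejects at ~3-4% at nominal 5%, the naive
paired t-test at ~50% — the classic anti-conservatism the correction
exists to fix.

## Problem sizes used by tests and the acceptance script

Unit tests run on 60- and 150-line panels with chains of 300-1,600 sweeps;
recovery and scenario checks use the study-scale panel (187 lines, 1,320
markers) with 10 seeds per condition and chains of 400/1,600 (bivariate)
or 300/1,000 (factor and accuracy fits). These sizes were chosen so the
whole suite completes in well under half an hour on one core while keeping
every stochastic assertion's Monte-Carlo error comfortably inside its
tolerance; defaults in the API remain at the full chain lengths
(5,000/20,000).

## Known limitations

* Genetic-correlation point estimates from a single biparental family are
  noisy and shrink toward zero; credible intervals (from the stored G0
  chains) should accompany any real inference.
* The factor model is a simplified MegaLMM-style sampler; it is not a
  drop-in replacement for the published package and its priors.
* No dominance or epistasis; no spatial adjustment; QC does no imputation
  beyond mean-fill and no LD pruning.
* The multi-environment runners treat environments as traits; explicit
  genotype-by-environment decompositions beyond the covariance structures
  offered are out of scope.
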