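# Methods

## Scope and model

`healthineq` measures wealth-related inequality in binary child-health
indicators from complex-survey microdata and decomposes it into covariate
contributions. The estimand chain is:

1. **Outcomes.** Full immunization (every dose of a configurable schedule
   documented by a dated card; the default schedule has 7 vaccines and 15
   doses — 1 BCG, 4 OPV, 3 pentavalent, 3 PCV, 2 rotavirus, 1 measles,
   1 yellow fever), food insecurity (dietary diversity score over 13 IYCF
   food groups below a threshold), and malnutrition (weight-for-age
   z-score strictly below −2 SD). Maternal recall without a dated card
   counts as *not* immunized: dated-card-only coding avoids recall bias at
   the cost of misclassifying children with lost cards.
2. **Ranking.** Children are ranked by the household wealth index score
   using weighted midpoint fractional ranks; tied scores form one block
   sharing the block's midpoint rank. This makes the weighted mean rank
   exactly 0.5 (the normalization the index formula presumes), renders
   ranks invariant to any strictly increasing transform of the score, and
   gives deterministic quintile cuts at weighted ranks 0.2/0.4/0.6/0.8
   with tie blocks assigned whole to the quintile holding their midpoint.
   When only quintile labels exist, ranks fall back to quintile-band
   midpoints; provided DHS quintiles can be passed through unchanged.
3. **Indices.** CI = 2·cov_w(h, R)/μ and ENCI = 4μ/(b−a)·CI. Weighted
   moments use the population form (divide by total weight), matching the
   index's sum-form definition; covariances therefore carry no n−1
   correction. Sign convention: positive = pro-rich.
4. **Uncertainty.** The convenient regression: the index equals the WLS
   slope of a rescaled outcome on the rank (algebraically identical to
   the covariance form — the suite checks agreement to 1e-10), so the
   cluster-robust sandwich grouped by PSU supplies the standard error.
   The rescaling treats μ and var_w(R) as fixed, the standard practice
   for this estimator. 95% intervals use ±1.96 (normal quantile; no
   degrees-of-freedom statement is attempted for many-cluster surveys).
   With a single record per cluster the cluster sandwich coincides with
   HC1; with a single cluster the estimator refuses and points to the
   unclustered fallback.
5. **Curves and dominance.** Ordinates L(p) interpolate the empirical
   cumulative-share step curve linearly, so an equally distributed outcome
   lies on the diagonal exactly. The dominance rule is the multiple
   comparison approach: per-point z = (L(p) − p)/se(p) at 19 interior
   quantile points (0.05…0.95), two-sided critical value at a
   Šidák-adjusted level (Bonferroni and no adjustment are options);
   ≥1 significant positive difference with none negative = curve
   dominance, the mirror = line dominance, both signs = crossing, none =
   non-dominance.
6. **Decomposition.** Weighted LPM of the outcome on the covariate design
   (same weights, ranks, and record subset as the index), contribution_k
   = 4·β_k·x̄_k·CI_k computed through the covariance form 8·β_k·cov_w(x_k,
   R) — identical when x̄_k ≠ 0 and still defined when x̄_k = 0, in which
   case the covariate's own CI is reported as NaN and flagged. The
   residual ENCI − Σ contributions equals 4× the generalized CI of the
   regression error; the adding-up identity is algebraic and the suite
   enforces it at 1e-10. Elasticity is β_k·x̄_k (not divided by μ): the μ
   division of the CI-scale decomposition is absorbed by the Erreygers
   factor 4μ, which is what makes 4·elasticity·CI_k reproduce published
   contribution cells directly.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `dd_threshold` | 4 | dietary diversity cut: score < 4 (≤3 groups) ⇒ food insecure |
| WAZ cutoff | −2 SD, strict | malnutrition boundary; strict and non-strict coding differ only at exactly −2 |
| `bounds` | (0, 1) | outcome range for the Erreygers factor |
| `alpha`, `n_points`, `adjustment` | 0.05, 19, Šidák | dominance test configuration |
| `encoding` | ordinal | one regressor per covariate (category codes); `dummy` expands levels |
| `weights_prenormalized` | False | skip the v005 ÷ 1,000,000 rescale for non-DHS inputs |
| age window | none | optional (min, max) months filter applied to the immunization analysis |

The dietary-diversity threshold is exposed because the minimum-diversity
convention admits two boundary readings; the default codes a score of at
most 3 groups as insecure, and any cut in 1..13 is reachable by config.
Missing data are handled by listwise deletion *per analysis*: each
outcome uses the rows complete for its own variables, so outcomes may have
different sample sizes, as survey analyses conventionally report.

## Synthetic generator

The generator emulates the structure of a DHS child recode, not any real
country: 20,000 children in 500 PSUs by default; latent log-wealth
z = √ρ·u_psu + √(1−ρ)·e with ρ = 0.3 (PSU share of wealth variance) and a
log-normal score exp(z); covariates linked to wealth through logistic or
ordered-cutoff models (urban residence, parental education in 4 levels,
ANC/PNC use, facility delivery, media exposure) or Poisson counts
(household size and birth order, wealth-negative); mother's age normal
(28, 6) truncated to 15–49; v005-scale weights log-normal with mean
1,000,000 and CV 0.3. Outcomes are Bernoulli draws from linear probability
models over those columns, clipped to [0.01, 0.99]; the default
coefficient vectors give a pro-rich immunization index (~+0.28) and
pro-poor food-insecurity (~−0.18) and malnutrition (~−0.23) indices —
gradients of the magnitude large national surveys show. Raw ingredients
(15 dose statuses, 13 food-group flags, WAZ with half-normal tails on
either side of −2) are generated consistently with the drawn labels, so
re-deriving outcomes from ingredients reproduces the labels exactly.
An optional PSU-level random effect on the outcome probabilities
(`outcome_cluster_sd`) induces within-cluster outcome correlation for
standard-error testing; by default cluster effects enter through wealth
only.

`population_truth` evaluates the generator's own population ENCI and
contributions by brute force on a 200,000-draw oracle, using the clipped
success probabilities in place of Bernoulli draws (removing outcome noise)
and a least-squares fit of the probability on the design (so the truth
accounts for clipping). The oracle draws ~40 children per cluster — the
marginal covariate law does not depend on the cluster count, and more
clusters shrink the oracle's own Monte-Carlo error.

What the generator does **not** emulate: two-stage PPS selection
probabilities (weights are independent noise), stratification,
non-response, informative missingness, measurement error in wealth or
anthropometry, and outcome-on-outcome dependence (e.g. malnutrition as a
regressor for food insecurity). Passing tests therefore demonstrate
estimator correctness under a clean complex-survey structure, not
robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

- The continuous standardized wealth regressor has weighted mean ≈ 0, so
  its *own* concentration index (which divides by the mean) is ill-scaled
  for display; report-level decompositions therefore default to the
  wealth quintile as the household-wealth regressor, while truth-recovery
  validation uses the generator's latent design. Contributions themselves
  are computed through the covariance form and are stable either way.
- A constant outcome yields CI = ENCI = 0 exactly (not merely close).
- Zero-mean outcome → undefined index, raised as an error; zero ordinate
  SE with a nonzero curve–diagonal difference → degenerate-variance error;
  rank-deficient designs are refused with the collinear columns named.
- Curve-ordinate standard errors use the influence-function variance of
  the cumulative share with the rank cutoff treated as fixed (clusters
  summed first when requested). For a binary outcome under the null this
  overstates the SE by ≈ (1−μ)^(−1/2), making the dominance test
  conservative: non-dominance is favored at the null, and power at
  n = 20,000 under a strong gradient remains essentially 1. A PSU
  bootstrap is available for honesty checks.
- ENCI numerically zero (|ENCI| < 1e-8) suppresses percent contributions;
  absolute contributions are still reported.
- Quintile assignment uses half-open bands (rank exactly at a cut point
  goes to the upper quintile), and tie blocks never straddle a cut.

## Problem sizes used by the test and acceptance suites

Parameter recovery runs 50 surveys of 20,000 children (500 PSUs) against
the 200,000-draw oracle; dominance calibration runs 200 null surveys of
2,000 children and 100 strong-gradient surveys of 20,000; the adding-up
identity is checked on 50 randomly drawn generator configurations; the
bootstrap SE comparison uses 1,000 PSU-resampled replicates on a 2,000
child survey. These sizes were chosen so each property is measured with
Monte-Carlo error well inside its tolerance.

## Known limitations

- The LPM decomposition is the exact-identity linear convention; probit
  or logit marginal-effects decompositions (which trade exactness for
  boundedness) are out of scope.
- Curve-vs-curve (two-sample) dominance between countries or years is not
  implemented; the test is one curve against the line of equality.
- Ordinal encoding of multi-level covariates matches the
  one-row-per-covariate reporting convention, but imposes equal spacing
  between adjacent levels; use the dummy encoding when that assumption is
  unacceptable.
- Weight-for-age z-scores are consumed, not computed: deriving WAZ from
  raw weight and age against growth standards is upstream of this
  package.
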