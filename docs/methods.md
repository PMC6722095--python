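# Methods

## The problem

A national educational-achievement (EA) test taken at the end of Dutch
primary school is scored on a 501–550 scale with a hard ceiling: every
child whose latent ability would map above 550 is recorded at exactly
550.  The national score distribution has mean 535 and SD 9 and is
negatively skewed because of that ceiling.  Twin cohorts scored on this
test support two complementary designs for studying how parental
socioeconomic status (SES) interacts with genetic differences:

* the **classical twin design**: monozygotic (MZ) pairs share all
  segregating alleles, dizygotic (DZ) pairs on average half, so the
  MZ/DZ difference in within-pair resemblance identifies additive
  genetic (A), common environmental (C) and unique environmental (E)
  variance components, which can then be allowed to differ across SES
  strata (group-wise gene–environment interaction);
* the **polygenic-score (PGS) design**: a standardized
  educational-attainment PGS per child supports between-family
  regressions of EA on PGS within SES strata, and — critically — a
  within-family contrast between DZ co-twins, who share their family
  and hence their parental SES, which removes confounding through
  genotype–SES correlation.

Both designs are biased by the ceiling unless it is modelled.  This
package's core is therefore a censored bivariate-normal pair likelihood
maximized by raw full-information maximum likelihood (FIML).

## Censored pair likelihood

A twin pair's latent scores are bivariate normal with means
(mu1, mu2), common variance v and covariance c.  With a fixed threshold
T = 550, the pair contributes according to its observation pattern:

| pattern                      | contribution |
|------------------------------|--------------|
| both observed                | bivariate normal density |
| one observed, one censored   | phi(y_obs) * P(latent co-twin > T given y_obs) via the conditional normal |
| both censored                | P(Y1 > T, Y2 > T), a rectangle probability |
| one observed, one missing    | univariate density (FIML keeps incomplete pairs) |
| one censored, one missing    | univariate survival PhiBar((T - mu)/sd) |

A stored score equal to T is *always* treated as censored; the flag is
derived on load, never trusted from input.  The 501 floor is applied in
the generator as plain clipping without a flag and is not modelled in
the likelihood: under all default parameter sets its probability mass
is below 1e-3 and its effect on any estimate is far below Monte-Carlo
resolution.

The rectangle probability P(Z1 > h, Z2 > k; rho) is computed from the
conditional form

    integral_h^inf phi(z) * PhiBar((k - rho z) / sqrt(1 - rho^2)) dz

by Gauss–Legendre quadrature on 8 fixed panels of 24 nodes over
(h, 10).  The integrand is a Gaussian times a smooth sigmoid, so this
fixed layout is exact to ~1e-14; the test suite verifies <1e-10
agreement with the orthant closed form 1/4 + arcsin(rho)/(2 pi), with
adaptive quadrature, with scipy's Genz CDF and with 10^7-draw Monte
Carlo.  |rho| = 1 uses closed forms (comonotone/antithetic), never
quadrature.

## Twin models

The model-implied pair covariance is a2 + c2 (MZ) or 0.5 a2 + c2 (DZ)
with total variance a2 + c2 + e2; the DZ additive-genetic correlation
is fixed at 0.5 (no dominance, no sex-limitation models — sex enters
the *means* only, as a per-twin covariate, which handles opposite-sex
DZ pairs naturally).  A `ModelSpec` declares which blocks are
stratified across the four SES groups: intercepts, sex effects, PGS
slopes, and the A/C/E components; the free-parameter count is a pure
function of the spec.  Twins in a pair share their group intercept.

**Optimization.**  Variance components are optimized on the
standard-deviation scale and squared inside the model, so nonnegativity
is a box bound and the C -> 0 boundary is reached cleanly (estimates of
exactly 0 are legitimate boundary solutions, mirroring how such
components are conventionally reported with 0.0 lower CI bounds).  The
unique-environment SD has a floor of 0.1 for identifiability.  Fits use
L-BFGS-B with finite-difference gradients from a moment-based start
plus four jittered restarts by default; the fit is flagged converged
when the optimizer succeeds and the two best restarts agree within
5e-4 in -2LL (a disagreeing restart triggers a confirmation re-solve
from the best point; an abnormal line-search termination at the
optimum is resolved by a derivative-free Nelder–Mead polish).  ACE
specs require both zygosities in the data — MZ pairs alone cannot
separate A from C.

**Model comparison.**  -2 log-likelihood is the canonical fit statistic.
Nested models are compared by the likelihood-ratio test: the -2LL
difference (clipped at 0) referred to chi-squared with df equal to the
difference in free-parameter counts.  Structural nesting is checked
from the specs and from fixed-parameter sets.  The pipeline reports
exact p-values and flags decisions at a configurable alpha whose
default is 0.01.  Note the usual caveat: for a variance component on
its boundary (the C test) the chi-squared(1) reference is conservative
(the asymptotic null is a 50:50 mix of chi-squared(0) and
chi-squared(1)); p-values are reported from chi-squared(1) as is
conventional in this literature.

**Confidence intervals** are profile-likelihood: the bounds where the
profiled -2LL rises by the chi-squared(1) quantile, bracketed
geometrically and solved by Brent's method, with variance lower bounds
reported as exactly 0.0 when even the zero-variance model stays inside
the quantile.  (Whether to use profile or Wald intervals was an open
choice; profile intervals are consistent with boundary-respecting 0.0
lower bounds and agree with Wald +-1.96 SE away from boundaries, which
a test verifies against a numerical-Hessian oracle.)

**Saturated twin correlations** use the exchangeable pair model (common
mean and variance, free correlation, optional sex effect) under the
same censored likelihood; on uncensored data the estimate coincides
with the exchangeable product-moment correlation.  Correlations can be
computed overall or per SES group (both are exposed; the pooled value
is inflated by between-group mean variance, which is itself part of
the phenomenon).

## PGS analyses

1. **PGS distribution by SES.**  Pair PGS values are modelled as
   Gaussian with MZ within-pair correlation fixed at 1 — an MZ pair
   carries one informative value — and a free DZ correlation.
   Stratified means/variances are tested against equated models
   (3-df LRTs).  The PGS is assumed already standardized and adjusted
   for ancestry/array upstream.
2. **EA on PGS in the twin model.**  Group intercepts and PGS slopes
   enter the means alongside sex; the residual variance is decomposed
   into A/C/E (stratified by default).  Slope equality
   (`equate_pgs_slopes`) and intercept equality (un-stratifying the
   means while slopes stay free) are 3-df LRTs.
3. **DZ PGS correlation** by exchangeable bivariate-normal ML with a
   profile CI.  Values above the biometrical 0.5 are consistent with
   assortative mating.
4. **Within-family contrast.**  Complete DZ pairs with both PGS and
   both EA are ordered within pair by PGS (exact ties dropped and
   logged); the means of the (higher, lower) pair are
   m_g +/- (delta + gamma * sexgap)/2 with per-SES baselines m_g, a free
   pair variance and correlation, under the censored pair likelihood.
   delta is the EA advantage of the higher-PGS co-twin; a 1-df LRT
   tests delta = 0.  The sex adjustment gamma is on by default (the
   exact historical parameterization of this test is ambiguous; this
   one matches the reported 1-df structure).  A sensitivity OLS of the
   EA difference on the PGS difference (and sex difference) is reported
   alongside.  Because m_g absorbs any group-level shift, the contrast
   is exactly invariant to adding a constant to an entire SES group —
   asserted on synthetic data.

## The synthetic cohort generator

The generator is first-class, tested code: every estimator has a
recovery test against its truth manifest.  Defaults encode the study
conditions the package is calibrated for:

* four SES strata with cell counts 320/1030/766/363 (MZ) and
  571/1859/1378/642 (DZ) pairs;
* girls' latent means rising 533.2 -> 542.0 across strata (reference
  point estimates), boys +1.3/+1.2/+1.2/+0.3;
* A/C/E components per stratum (65.9, 2.7, 17.9) -> (47.8, 0.0, 11.2),
  falling with SES;
* PGS stratum means (-0.3, -0.1, 0.1, 0.3) — a genotype–SES
  correlation of realistic size, chosen to reproduce a strongly
  significant 3-df mean test at the reference sample size — unit
  variance, DZ within-pair correlation 0.5 (configurable up to 1 to
  mimic assortment; no explicit mating model);
* beta_pgs = 2.85 score points per PGS SD, a calibration constant that
  lets the PGS account for ~10% of EA variance, consistent with
  published attainment-PGS performance; it is not an empirical
  estimate;
* right-censoring at 550, floor clipping at 501, 14% incomplete pairs.

`ace_variances` are **total** components: the PGS-tagged genetic share
beta^2 * var(PGS) is carved out of A internally, so an ACE fit that
ignores the PGS recovers the configured components exactly, and at DZ
PGS correlation 0.5 the classical MZ/DZ covariance algebra is
untouched (at 0.55 the DZ covariance gains a negligible
0.05 * beta^2 ~ 0.4 score-units^2).

**Level calibration.**  The stratum means are reference estimates from
a register sample that over-represents high-SES families; their
weighted mean sits ~2.9 points above the national mean of 535.  The
default configuration therefore subtracts one computed constant from
all four stratum means so the cohort-weighted latent mean equals the
national 535 exactly, preserving every contrast and variance component.
The implied marginal SD is 8.95 and the censored fraction rises from
~2% (lowest SES) to ~9% (highest), reproducing the SES-graded ceiling.

Sampling is deterministic given the seed, with named substreams (PGS,
genetics, sexes) so toggling missingness never perturbs the drawn
cohort.  Sexes: MZ pairs share one Bernoulli(1/2) draw; DZ twins draw
independently, giving the realistic 50% opposite-sex share.

**What the generator does not emulate** — and hence what passing
recovery tests do not establish about real data: no genotypes or LD
(the PGS is drawn directly as Gaussian), no skew beyond what censoring
induces (real scores are discrete and irregularly skewed), missingness
is completely at random (real non-response is SES-graded), no dominance
or sibling-interaction effects, no explicit assortative-mating
mechanism, and SES is error-free.

## Pipeline and problem sizes

`run_analysis_ladder` executes: total-sample ACE; C-significance;
SES-stratified means with per-group sex tests and the C-after-SES test;
SES-stratified variances (the 9-df moderation test); then, when PGS
data are present, the PGS distribution tests, EA-on-PGS slope and
intercept equality, the DZ PGS correlation and the within-family
contrast.  Every reported number comes from a persisted fit, and the
JSON report is byte-deterministic given the data and seed.

Verification problem sizes were chosen so each check resolves its
target within Monte-Carlo error on a single CPU: recovery experiments
use 5000–6000 pairs (50 replicates where a mean is asserted), kernel
Monte Carlo uses 10^7 draws, and LRT calibration uses 1000 replicates
of ~1000-pair cohorts generated under correctly specified nulls
(boundary-free tests only; the C = 0 boundary test is excluded because
its null is the chi-squared mixture noted above).

## Known limitations

* Chi-squared(1) p-values for boundary (C) tests are conservative.
* The pooled (non-stratified) C estimate is a 2 covDZ − covMZ contrast
  and correspondingly noisy; stratified analyses are the headline.
* Profile CIs refit the model per probe point; computing them for a
  full stratified model is 1–2 orders of magnitude more expensive than
  the fit itself (hence opt-in in the pipeline).
* The within-family contrast conditions on PGS order but ignores
  measurement error in the PGS; with noisy scores the gap attenuates.
* No weighting for the register's SES composition: estimates describe
  the cohort analysed, not the national population.
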