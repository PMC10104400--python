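# Methods

## The twin model

The package implements the classical twin design for quantitative
phenotypes. Each phenotype y is modelled, after covariate adjustment, as
y = aA + cC + eE with standard-normal latent factors: A (additive genetic)
correlates 1.0 within monozygotic and 0.5 within dizygotic pairs, C
(shared environment) correlates 1.0 within all pairs, and E (unique
environment, which also absorbs measurement error) is uncorrelated across
co-twins. A pair's phenotype vector is bivariate normal with common mean
and covariance a² + c² (MZ) or ½a² + c² (DZ); unmatched twins contribute
the marginal normal likelihood of their single observation
(missing-at-random). Paths are estimated as coefficients and squared for
reporting, so variance components are nonnegative by construction, and
standardised proportions a²/(a²+c²+e²) etc. are reported. Dominance
(ADE) and sex-limitation models are out of scope: the two-group (MZ/DZ)
ACE family is the entire model space.

The bivariate extension models the per-family vector (x₁, y₁, x₂, y₂) as
4-variate normal. Each source contributes a 2×2 within-person covariance
Σ_S; the cross-twin block is w·Σ_A + Σ_C with kinship weight w = 1 (MZ) or
0.5 (DZ). Two parameterisations are fitted:

* **Cholesky**: Σ_S = L_S L_Sᵀ with lower-triangular L_S (diagonals ≥ 0 as
  the sign convention). The likelihood is order-invariant; the
  common/specific reading of a trait is taken from the run in which it
  comes second, hence the model is conventionally run in both orders.
* **Constrained independent pathway**: one common factor per source with
  loadings tied equal across the two traits (the default identification
  scheme), plus trait-specific factors. The two-group bivariate design
  supplies 9 distinct structural moment conditions (3 within-person, 3 per
  cross-twin block), so constraint sets leaving more than 9 free
  covariance-structure parameters are rejected before optimisation.
  Tying loadings equal forces a nonnegative cross-trait covariance, so
  negatively associated traits (duration vs midpoint) are handled by
  sign-flipping one trait first (`flip_trait`); the pipeline records the
  flag. Note that equal raw loadings also force the common variance of the
  two traits to be equal in raw units — unequal common *shares* can arise
  only through unequal total trait variances.

Correlations are decomposed as rG = Σ_A(x,y)/√(Σ_A(x,x)Σ_A(y,y)) and
analogously for rC and rE; each source contributes
Σ_S(x,y)/√(v_x v_y) to rP and the contributions sum to rP exactly. A
source with (numerically) zero variance in either trait reports NaN for
its correlation.

## Estimation and numerics

All fits minimise the exact multivariate-normal −2 log-likelihood with
full-information handling of missingness: families are grouped by
missingness pattern once per dataset and each pattern's contribution is
evaluated in closed form (Cholesky factorisation of the sub-covariance;
vectorised quadratic forms). Optimisation is bounded L-BFGS-B on path
coefficients with 5 jittered random restarts by default (the likelihood is
sign-invariant in the paths, so squaring plus nonnegativity bounds removes
the ambiguity), started from moment estimates — the correlation-algebra
closed form in the univariate case and the DeFries–Fulker-style source
covariances Σ̂_A = 2(B_MZ − B_DZ), Σ̂_C = 2B_DZ − B_MZ (eigenvalue-clipped
to PSD) in the bivariate case. A final Nelder–Mead polish removes the
finite-difference gradient noise floor, which matters for the
oracle-equivalence and order-invariance tolerances (1e-6). Invalid
covariance regions return a large finite penalty rather than infinity so
numerical gradients stay defined. The E-only model is closed form. The
saturated models (univariate per-zygosity means/variances/correlations
with optional equality constraints; unstructured 4×4 bivariate baseline)
use the same machinery.

Model comparison uses AIC = −2lnL + 2·(free parameters) with ties broken
toward fewer parameters, plus likelihood-ratio p-values of each sub-model
against ACE. Tests of components on the boundary (a² = 0, c² = 0) use the
naive χ² reference and are therefore conservative.

Confidence intervals are profile-likelihood based: a 95% interval for a
standardised component is the set of values whose profile −2lnL rises at
most χ²₁(0.95) = 3.841 above the minimum, bounded at the parameter limits
0 and 1. The profile fixes the component's share and re-optimises total
variance, the split of the remaining share, and the mean. Coverage is
checked by simulation via the equivalent deviance criterion (truth covered
iff its profile deviance ≤ 3.841), which needs one constrained fit per
replicate.

The closed-form correlation oracle (a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ,
e² = 1 − rMZ) serves as an independent check: on data whose ML sample
moments equal a population ACE structure exactly, the ML fit must
reproduce it to optimiser precision. Negative oracle components are
clamped to zero with a warning and no refit, so clamped outputs may sum to
less than one.

## Sleep-measure extraction

Sustained inactivity is a maximal run of 5-second epochs whose arm angle
changes by at most 5° from one epoch to the next, lasting at least 5
minutes (≥ 60 epochs); "angle change" is the absolute difference between
consecutive epoch angles. Runs are intersected with the diary sleep
window; clipped fragments shorter than 5 minutes are retained because the
sustained rule applies at detection, before windowing. Onset is the start
of the first sleep period, wake the end of the last, duration the sum of
period lengths, midpoint halfway between onset and wake (not weighted by
within-night wakefulness). The diary's morning response is coded
Refreshed = 1 / Tired = 0; a night with no sleep periods is flagged
missing rather than erroring. The detector is invariant to adding a
constant to all angles, and requires strictly regular 5-s epoch spacing.

Clock times use a continuous minutes-from-noon axis (21:51 → 591,
01:11 next day → 791), because onset distributions span midnight and
naive clock arithmetic breaks means and differences.

## Preprocessing

Nights are dropped when device data are missing or when |device onset −
diary bedtime| exceeds 6 hours; a disparity of exactly 6 h is retained
(the exclusive reading drops fewer data). Subjects with fewer than 7
retained nights of the 14-night window are removed. Subject-level means
are computed over all nights and separately for school and nonschool
nights (nights preceding weekends or holidays); restorative sleep becomes
the percentage of nights coded refreshed. Phenotypes are z-scored over
available subjects; |z| > 4.00 is set missing first, then survivors with
|z| > 3.29 are pulled to the threshold, in a single pass without
recomputing z-scores — a deterministic reading, idempotent up to the
removed entries. Age and sex are removed by OLS within each analysis
sample (full, younger, older), ignoring family clustering at this stage;
the familial covariance is modelled downstream. Subjects with no school
nights enter school/nonschool bivariate models through the missing-data
likelihood.

## The synthetic-data generator

Defaults encode the study conditions the analysis targets: 93 MZ + 117 DZ
pairs plus 75 unmatched twins, ages uniform on 9–17 (55% female), 14
nights, ACE proportions 0.62/0.08/0.30 (the full-sample sleep-duration
values). Kinship correlations are exact by construction: per-family A
(shared for MZ; √½·common + √½·segregating for DZ), per-family C,
per-individual E. The night model anchors onset at 21:51 (between-subject
latent SD 50 min, nightly noise SD 45 min), wake at 06:46 (SD 36/40 min),
with nonschool delays of 25 and 15 min, age delays of 14 and 6 min/yr, a
−15 min male effect carried on wake (so duration is ~15 min shorter for
males), and restorative sleep on ~44% of nights via a subject-level logit
whose latent is the ACE draw. The latent/nightly SD split was chosen once
so that subject-mean SDs land near 1:00 (onset) and 0:42 (wake) after the
age effect is included. The school calendar is a repeating 7-day template
(configurable start weekday and holiday blocks, so an all-holiday
participation window is expressible); nights preceding Saturday/Sunday
mornings or holidays are nonschool. Missing device nights (default 5%)
and gross (> 6.5 h) diary/device disparities (default 1%) are injected at
configurable rates. Default seed 20211022; every stochastic operation
takes an explicit seed, and fixed seeds reproduce outputs byte for byte.

The angle-trace generator holds the epoch-to-epoch change inside the 5°
threshold during sleep (uniform jitter), emits super-threshold posture
changes at the configured rate while awake and always during brief
arousals, and places deterministic posture shifts at the sleep/wake
transitions; diary times are truth plus zero-mean noise. Ground truth is
returned with the trace, so detector error is measurable; at zero noise
extraction recovers onset and wake exactly.

What the generator does **not** emulate: raw 30 Hz accelerometry (it
emits the derived angle series directly), within-night sleep-stage
structure or posture physiology, correlated familial structure *across*
phenotypes at the night level (each phenotype draws its own ACE latent;
cross-trait structure is exercised through the dedicated bivariate
generator), non-normal phenotype distributions, and informative
missingness (nights are missing completely at random). Passing recovery
tests therefore demonstrate correctness of the estimators under the
model's assumptions, not robustness to their violation in field data.

## Reported problem sizes

Parameter-recovery summaries use 200 replicates at the study's 93+117
pair size; the covariate-recovery summary uses 100 cohorts of 400
subjects; profile-CI coverage uses 500 replicates at 200+200 pairs;
large-sample moment checks use 50k–100k pairs. These sizes put Monte
Carlo error well inside the tolerances asserted (e.g. SE ≈ 0.01 for the
mean of 200 â² estimates). At 93+117 pairs the nonnegativity-bounded ML
estimator shows the known small-sample downward boundary bias
(mean â² ≈ 0.59 under a true 0.62); this is a property of the bounded
estimator, not of the generator.

## Known limitations

* Boundary p-values and AIC comparisons ignore the mixture distribution
  of boundary likelihood-ratio statistics.
* The equal-loadings independent-pathway model cannot represent opposite-
  sign common loadings; the sign flag handles the overall direction but
  not mixed-sign structures.
* The saturated bivariate baseline estimates 28 parameters and can be
  slow to converge tightly on small samples; it is used as a likelihood
  floor, not for reporting.
* OLS residualisation ignores family clustering, which is harmless for
  point estimates of fixed effects but makes their reported standard
  errors slightly optimistic.
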