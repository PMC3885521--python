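# Methods

## Model and procedure

`pai` estimates individualized treatment recommendations from a completed
two-arm randomized trial with a continuous end-of-treatment severity
outcome.  The statistical model is an ordinary Gaussian linear model on the
transformed outcome z (by default z = √y, which stabilizes the right-skew
typical of end-of-treatment symptom scores and renders residuals
approximately normal; an identity option exists for outcomes that are
already well behaved):

    z = β₀ + Σⱼ βⱼ xⱼ + β_T T + Σ_k γ_k (T·x_k) + ε,   ε ~ N(0, σ²)

- prognostic covariates enter as main effects only;
- prescriptive covariates (moderators) get a main effect *and* a
  treatment interaction;
- Kraemer coding throughout: the treatment indicator T and all dichotomous
  covariates are coded ±½ (first-listed arm +½), 3-level ordinals −1/0/+1,
  counts are capped then mean-centered, continuous covariates mean-centered.
  Under this coding β_T is the average treatment effect at the mean
  covariate profile and interaction columns are near-orthogonal to mains.

Estimation is exact least squares (`numpy.linalg.lstsq`), not iterative;
the model is Gaussian-linear and OLS is its maximum-likelihood fit.  The
term set is fixed by the user's variable declarations and never re-selected
inside resampling folds — moderator *discovery* is explicitly out of scope;
roles are inputs.

Predictions are leave-one-out: for each patient the model is refit on the
remaining n−1 patients and the patient's endpoint is predicted under both
arms, the counterfactual arm obtained by flipping the sign of the treatment
code in the treatment main-effect and every interaction term (identically:
rebuilding the design row under the other arm).  Predictions are squared
back to outcome units; negative linear predictions clamp to 0 first because
severity scales are bounded below.  The PAI is the absolute difference
between the two arm-specific predictions; the Optimal arm is the one with
the strictly better prediction ("none" on an exact tie, in which case the
patient is excluded from group comparisons).  Lower-is-better is the
default outcome direction, with a flag for benefit-scored outcomes.

## Evaluation

- **True error**: mean absolute difference between observed endpoints and
  leave-one-out factual predictions.
- **Standard error of prediction**: the root-mean-square error is the
  reported default; the sample SD of the errors is computed alongside as an
  alternate definition, since "standard error of prediction" is used
  ambiguously in the applied literature.  Neither is privileged by the
  method itself.
- **Optimal vs Non-optimal comparison**: a pooled-variance two-sample
  t-test on observed endpoints (Welch available by flag), with mean
  difference oriented Non-optimal minus Optimal so positive values favor
  index-guided assignment.  Cohen's d = mean difference / pooled SD; its
  95% CI comes from inverting the noncentral-t distribution, the exact
  interval for a standardized mean difference.  It is asymmetric around d,
  unlike the normal approximation, which matters at moderate group sizes.
- **Clinical-significance threshold**: patients with PAI ≥ 3 outcome
  points (the NICE criterion for a clinically significant HRSD difference)
  form the "significant" subsample, evaluated separately; the threshold is
  configurable and the boundary is inclusive.
- **Baseline balance**: t-tests for continuous/capped-count covariates and
  chi-square tests (no continuity correction) for dichotomous/ordinal ones,
  per arm, as a randomization check.  Degenerate tables are flagged, never
  fatal.

## Centering constants

"auto" centering constants are resolved as fitting-sample means, computed
once on the full sample by default; a `per_fold` option recomputes them
inside each leave-one-out training set.  Predictions and PAIs are invariant
to this choice (and to any fixed shift of the centering constants) because
shifted interaction columns stay within the span of the included mains and
treatment column — a property the test suite verifies to 1e-8 — so the
default favors the interpretability of a single coefficient table.
Per-fold centering only affects reported fold residual SDs.  For capped
counts the constant is the mean of the *capped* variable (capping precedes
centering).

The bundled worked example uses fixed centering constants (intake HRSD
23.75, age 40.33, life stressors 3.65, capped prior trials 0.72): a
reference coefficient table is only portable to a new patient together with
the constants under which it was estimated, so the example fixture pins
them rather than recomputing means from its single row.

## Synthetic-data generator

The generator emulates a 154-patient CBT (n=50) vs ADM (n=104) depression
trial so that every pipeline stage is testable without access to clinical
data:

- **Arm assignment**: exact-count permutation (50/104), mirroring fixed
  trial allocation, not Bernoulli.
- **Covariate marginals** (drawn independently; no correlation structure by
  default): intake HRSD ~ N(23.8, 3.2²), age ~ N(40.3, 11.3²),
  IQ band low/middle/high with probabilities .156/.526/.318, chronic course
  55.2%, married 37.7%, employed 85.1%, comorbid personality disorder
  48.1%, prior medication trials with mass .52/.24/.24 on 0/1/2+ (capped at
  2), and life stressors from a negative binomial matched to mean 6.6 and
  SD 4.8 (a Poisson cannot carry that overdispersion).
- **Outcome**: transformed outcome = true linear predictor + N(0, σ);
  endpoint = clamped square.  Default coefficient truths are the bundled
  reference coefficient set, so the default synthetic world resembles the
  motivating trial.
- **Residual SD**: σ = 0.90 on the √ scale, calibrated once by simulation
  so that the leave-one-out true error of the default trial sits near 4.9
  HRSD points, a typical error magnitude for this endpoint at this sample
  size.

What the generator does *not* emulate: covariate correlations (an optional
hook exists), dropout/missingness (the method is defined for completers),
measurement error in covariates, and site or therapist effects.  Passing
tests therefore demonstrate the correctness and calibration of the
*procedure*, not the real-world replicability of any particular moderator
set.

**Floor effects.** Because endpoints are clamped at 0, the synthetic world
floor-censors roughly 1–2% of draws under the default coefficients.  This
is realistic (HRSD cannot go below 0) but means OLS on √y is not exactly
unbiased for the generating coefficients at very large n.  Ground-truth
recovery tests therefore use an uncensored configuration (identity scale,
intercept far from the floor) and assert that no draw touched the floor, so
the linear regime is verified rather than assumed.

## Null calibration

`null_calibration_study` measures whether the pipeline can manufacture
spurious benefit: in a world where treatment assignment has *no* effect on
any patient's outcome (treatment main effect and all interactions zero),
Optimal-arm labels are driven purely by noise in the estimated interaction
coefficients, and — because each patient's label comes from a fold model
that never saw that patient's outcome — the Optimal/Non-optimal effect size
d must average to zero.  Over 200 replicates at n = 150 the mean d is
−0.005 (Monte-Carlo SE 0.017).  Note that zeroing the interactions alone is
*not* a null world: with a nonzero treatment main effect the model
(correctly) predicts the same better arm for nearly everyone, and d
honestly estimates the average treatment effect (≈ 0.24 under the default
main effect).  A large injected interaction (γ = −2.5 on one moderator)
drives the mean d strongly positive (≈ 1.0), confirming power.

Replicates whose random draw is degenerate — a rank-deficient fold (e.g. no
unemployed patient left in one arm, making an interaction column collinear;
about 0.5% of draws at n = 150) or an empty comparison group — produce no
effect size; they are discarded, replaced from the same seed stream and
counted (`CalibrationStudy.n_degenerate`).

## Numerical choices and edge cases

- Rank deficiency raises an error naming the collinear terms (pivoted QR);
  leave-one-out folds report which fold failed.
- Exact prediction ties propagate `optimal_arm = "none"` and
  `received_optimal = "indeterminate"`; such patients count in the
  below-threshold group and are excluded from group comparisons.
- Fitting requires strictly more observations than terms and complete
  cases; any missing covariate or (in fit mode) endpoint is rejected with
  row/column coordinates.  No imputation.
- Residual normality is checked with a Shapiro–Wilk test at α = 0.05,
  reported but never blocking — it motivates the √ transform, nothing else.
- Predictions CSVs are written at 4 decimal places; summary JSON at full
  precision with sorted keys.  All randomness descends from one seed;
  identical invocations are byte-identical.
- The `summarize_endpoint` helper averages the final two visit scores (by
  week order) to smooth end-of-treatment fluctuation; a single available
  score is used as-is — a pragmatic fallback for sparse follow-up, chosen
  here, not a property of the method.

## Problem sizes used in the test suite

Oracle-agreement checks run 50 random trials of total n ≤ 60 against an
independent per-fold refit via statsmodels; ground-truth recovery uses one
n = 10,000 trial; calibration studies use 200 replicates at n = 150.  These
sizes give Monte-Carlo error comfortably below the assertion margins while
keeping the full suite around two minutes on one core.

## Known limitations

- Exactly two arms; no survival, binary or repeated-measures endpoints.
- Linear model with user-fixed terms: no shrinkage, interaction selection,
  or flexible learners; with many weak moderators the PAI can overfit noise
  (the null-calibration study bounds the *average* bias at zero but not the
  dispersion of individual PAIs).
- The Optimal/Non-optimal comparison evaluates the selection rule under the
  trial's own randomization; prospective benefit in a new population
  additionally requires the moderators to replicate.
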