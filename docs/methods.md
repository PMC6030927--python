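# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The two-stage landmark model

**Cohort and timescale.** Ages are exact fractional years,
(date − birth date)/365.25 days. Study entry is the latest of: registration
date + 6 months, the practice's acceptable-computer-usage date, its
acceptable-mortality-reporting date, the 30th birthday, and the study start
(1997-01-01 by default); exit is the earliest of: first CVD event, transfer
out, death, and the study end (2016-01-18). Patients are excluded for
missing birth date, unknown sex, CVD or a statin prescription at or before
entry, entry after age 85, non-positive follow-up, and absence of any
marker measurement between entry and exit; each count is logged in the
cohort-flow record. Implausible measurements are removed (SBP outside
[60, 250] mm Hg, total cholesterol outside [1.75, 20] mmol/L, HDL-C outside
[0.3, 3.1] mmol/L; strict inequalities, boundary values kept). SBP, total
cholesterol and HDL-C are standardized to sex-specific z-scores whose
mean/SD come from each person's first post-entry measurement, so frequent
attenders do not dominate the scale; the parameters are frozen and reused
on held-out folds.

**Landmark eligibility and boundaries.** At landmark age s a patient is
eligible iff entry_age ≤ s < exit_age with no CVD event and no statin at or
before s. A measurement at exactly age s belongs to the history; an event
at exactly s makes the patient ineligible. These conventions guarantee
strictly positive follow-up times. History is restricted to ages in
[30, s]; follow-up is capped at 10 years (administrative censoring at the
horizon), so proportional hazards is only assumed within the 10-year
window.

**Stage 1.** Per landmark age and sex, the four markers are modelled
jointly with fixed intercepts and slopes on t = age − s (t ≤ 0), a
treatment indicator on SBP rows (carry-forward "on blood-pressure-lowering
medication at measurement time"), and correlated random intercepts
b_i ~ MVN(0, G) with independent residuals. Centering time at the landmark
makes the (fixed + random) intercept the current value at s, avoiding a
slope-extrapolation step. Random slopes are deliberately absent — fixed
slopes capture population drift, matching the random-intercept structure
the framework assumes. Smoking is treated as a continuous Gaussian outcome
(the multivariate-normality assumption extends to the binary marker, a
standard simplification also used in regression calibration); predicted
smoking values are not clipped before entering the Cox model.

Estimation is marginal maximum likelihood (REML available as a spec
switch). Because the random effects are intercepts only, the per-person
marginal covariance V_i = Z_i G Z_i' + R_i yields, via the Woodbury
identity, a likelihood that depends on the data only through per-person,
per-marker sufficient statistics (counts, design cross-products and sums),
so one likelihood evaluation is O(n_persons) in 4×4 algebra regardless of
measurement counts. G is parameterized by its Cholesky factor with
log-diagonal, residual variances by their logs; fixed effects are profiled
by GLS (with a pseudoinverse fallback for rank-deficient designs, e.g. a
marker observed at a single time point). Optimization is L-BFGS-B with two
starts (a moment-based variance decomposition and a diagonal-G start);
convergence declared at the optimizer's default ftol 1e-11 / gtol 1e-6 and
reported in the fit metadata. Markers with no measurements in a stratum are
reported inestimable (NaN parameters), never silently defaulted.

**BLUP prediction.** For any person (in- or out-of-sample) with any subset
of observed markers, b̂_i = G (I + A_i G)⁻¹ w_i, where A_i is the diagonal
of per-marker counts over residual variances and w_i the residual sums over
residual variances. Persons with no in-window measurements receive the
fixed-effects (prior-mean) prediction, which keeps the full eligible cohort
in stage 2 — the framework's population-screening rationale. The identity
is valid for singular G and is verified against direct conditional-MVN
computation to 1e-8 in the tests.

Sensitivity options: a finite lookback window (default ∞, 10 years as the
sensitivity value) and a per-marker annual visit-rate covariate (the rate
in the 5 years before s, window truncated at age 30) as a proxy for
visit-intensity confounding.

**Stage 2.** The per-landmark covariate tables are stacked
(one row per eligible (patient, landmark age)) and a single Cox model is
fitted with time-since-landmark as the clock, stratified by sex, with
Breslow tie handling. Landmark age enters as z = (s − 60)/10 and z² (so
age hazard ratios are per decade; the centering/scaling is for optimizer
conditioning and is documented rather than back-transformed). Breslow ties
were chosen over Efron deliberately: under Breslow, duplicating every row
of the stack (the same person and the same event legitimately recur across
landmark ages) leaves the estimate and the patient-clustered sandwich
variance *exactly* unchanged, which is the correct invariance for
super-landmark data; Efron violates it under the ties that stacking
creates. The fit is Newton–Raphson with step halving on analytic
score/hessian; monotone likelihood (perfect separation) raises an error at
|θ| > 50. Robust variance clusters score residuals by patient (a practice-
level option would be a trivial change of the cluster key). The baseline
cumulative hazard is the per-stratum Breslow estimator; 10-year risk is
1 − exp(−Λ₀,sex(10) e^{x'θ}).

Model variants: `basic` (z, z², diabetes, bp-treatment), `current_values`
(adds the four stage-1 values), `age_interactions` (every covariate also
multiplied by z), `last_observed` and `cumulative_mean` (the respective
history summaries; rows missing any marker are dropped — the restricted
sample).

## Validation

* **Brier score** (default IPCW): events by the horizon weighted by
  1/Ĝ(T⁻), subjects followed past the horizon by 1/Ĝ(10⁻), censored-before-
  horizon subjects weight 0, with Ĝ the Kaplan–Meier estimator of the
  censoring distribution. The naive complete-case average is also reported
  since the two coincide exactly when no one is censored before the
  horizon. Both are reported because the defensible estimator under
  censoring is IPCW while the plain mean squared difference is the simpler
  published definition.
* **C-index** (Harrell): comparable pairs are pairs of *different*
  individuals (same-patient pairs across landmark ages are excluded) whose
  order is determinable under censoring; score ties earn 1/2. Under tied
  times with exactly one event, the event member should carry the higher
  score; tied times with two events are omitted. The age-adjusted version
  restricts comparisons to same-landmark-age pairs and is also pooled
  across ages weighted by comparable-pair counts.
* **Calibration**: mean predicted risk vs 1 − KM(10) by decile of
  predicted risk; empty bins produced by tied predictions are merged with
  a warning.
* **Cross-validation**: practices (never individuals) are split into k
  folds; standardization, stage-1 and stage-2 parameters come from the
  training practices only; held-out persons get out-of-sample BLUPs from
  the training stage-1 parameters and risks from the training Cox fit;
  metrics pool all held-out predictions. A guard raises rather than
  fitting stage-1 on a held-out fold if a training fit is missing.
* **Model comparison**: ΔC-index and ΔBrier vs the basic referent with
  percentile CIs from a nonparametric bootstrap that resamples patients
  (all their stacked rows together, re-keyed so duplicates act as distinct
  clusters); 200 replicates by default, fewer in the demo for runtime.

## The synthetic generator

No real primary-care data can be shipped, so the generator produces
registry and measurement tables with the statistical structure the model
assumes. Per patient (each with a deterministic RNG substream derived from
(seed, index), so growing the population preserves earlier patients):

* registration date uniform in the practices' electronic era (1987–2010),
  registration age truncated-normal (mean 45, SD 14, min 18), birth date
  derived and clamped to 1930–1975; practice quality dates drawn in
  1992–1998; transfer-out and death exponential (0.045/y, 0.004/y from
  registration); administrative end 2016-01-18. These choices give a mean
  study-entry age ≈ 47.5 years and a study-sample fraction ≈ 77%.
* latent marker trajectories on the standardized scale:
  y = β0 + β1·age + γ·bpmed·[SBP] + b + ε, with defaults: SBP rising
  0.025 SD/y, total cholesterol 0.018 SD/y, HDL-C and smoking slowly
  falling; G with moderate positive SBP–cholesterol and negative HDL-C
  correlations; residual variances roughly half the person-level variance
  for SBP (measurement noise dominates single SBP readings);
  γ = −0.4 SD ≈ −8 mm Hg. Raw units come from fixed location/scale maps
  (SBP 134.8/21.0 mm Hg, TC 5.5/1.1, HDL-C 1.4/0.4 mmol/L). Smoking is
  emitted continuous (linear-Gaussian, the stage-1 exact-model case) or as
  a 0/1 threshold variable for robustness checks.
* visits: independent homogeneous Poisson processes per marker at rates
  1/1.1, 2.0, 1/1.1 and 1/1.2 per year (smoking, SBP, TC, HDL-C), matching
  the observed mean inter-measurement gaps; an optional shared
  consultation process is available for correlated missingness but the
  default is independence.
* conditions/treatments: exponential clocks from age 30 (diabetes 0.011/y,
  bp medication 0.030/y) and from the statin era 1995 (statins 0.016/y,
  ≈17% of the study sample over follow-up).
* events: hazard λ0,sex(a)·exp(θ'x_true(a)) with Gompertz baseline
  (log-slope 0.062/y; rates at age 30 of 4.5e-4 (men) and 3e-4 (women))
  acting on the true current covariate values. Because the continuous part
  of the log hazard is linear in age, event times are drawn exactly by
  inverting a piecewise-Gompertz cumulative hazard with breakpoints at the
  diabetes/bp-medication onsets. The log hazard ratios default to
  field-typical values — smoking 0.70, SBP 0.48/SD, TC 0.27/SD, HDL-C
  −0.38/SD, diabetes 0.65, bp treatment 0.15 — which also give the
  sign-only current-values-vs-basic comparison realistic power at the demo
  scale; the baseline rates are calibrated so the 10-year landmark event
  fraction is ≈7%.

**What the generator does not emulate:** informative observation
(visit intensity independent of health status), calendar trends in
prescribing, practice-level heterogeneity beyond the practice label,
non-Gaussian marker distributions, measurement error correlated across
markers within a visit, and competing risks (death censors). Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions — parameter recovery, oracle agreement, leakage-free
validation — not transportability to real EHR data.

## Problem sizes and numerical choices

The demo/validation configuration is 2,000 patients in 10 practices,
landmark grid 40–85 by 5, 10-fold cross-validation by practice; it yields
≈1,550 study-sample patients, ≈2,500 stacked rows and ≈100 events, and
runs in about two minutes on one CPU. Parameter-recovery simulations use
n=1,000 (stage 1, 20 replicates) and n=5,000 (stage 2, true-covariate
check within 3 MC standard errors). With ≈100 events per replicate the
cross-validated ΔC-index of a single run is noisy, so the sign comparison
is evaluated on the mean over three demo-scale replicates; bootstrap CIs
in the demo use 50 replicates (200 is the library default).

Other numerics: BLUP linear systems raise with conditioning diagnostics
beyond condition number 1e12; boundary tolerances of 1e-12 are used for
age-window inclusion; the Newton Cox fit declares convergence at step
max-norm < 1e-10 and gradient max-norm < 1e-6.

## Known limitations

* Uncertainty in the stage-1 current values is not propagated into the Cox
  model (estimated BLUPs are treated as known covariates).
* The Brier/C-index bootstrap is percentile-based and clustered on
  patients; practice-level clustering of the CIs is not implemented.
* The "future 10-year average risk factor" variant, time-dependent statin
  modelling, and joint longitudinal–survival models are out of scope.
* The generator's visit processes are non-informative by design; the
  visit-rate adjustment option can be exercised on synthetic data but its
  confounding-correction value cannot be demonstrated there.
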