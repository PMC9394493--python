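# Methods

## The prediction problem

Roughly half of the recruits entering a 24-week military basic-training
programme leave before completing it. `dropmark` implements a dynamic
(time-updated) prediction pipeline for that attrition process: given a
recruit's fixed entry characteristics and their weekly self-reported mental
and physical health status, it estimates the conditional probability of
dropping out in the coming week(s), updated as new weekly reports arrive.

## The landmarking supermodel

The follow-up period is divided into S = 23 nonoverlapping weekly landmarks
at days 7s, s = 1..S (a 24-week course has one landmark at the end of every
week except the last). At landmark s a dataset is formed from all recruits
still in training at day 7s whose covariates are observable by then; the
hazard of dropout for recruit i in the window (7s, 7(s+1)] is

    h(t | Z_i(s), s) = h0(t) · exp( Z_i(s)·(β1 + β2·code(s)) + X_i·γ )

where X_i are 9 baseline terms (height, body mass, age, two education
dummies with "unknown" as reference, body-fat %, Cooper-test distance,
push-ups/10, sit-ups/10), Z_i(s) are 6 time-varying terms (five 10-point
Likert items — general health, motivation, absence of muscle soreness,
sleep quality, physical fitness — plus a dichotomized musculoskeletal-pain
indicator), and the β2 interactions let the weekly effects drift across
landmarks. The landmark datasets are stacked and all 21 coefficients are
estimated from one pooled Cox partial likelihood; because the windows
partition the timescale, a single day-level likelihood with (start, stop]
risk intervals forms the correct within-window risk sets automatically.

**Interaction coding.** `code(s) = s − 1` by default, so the main effect
β1 is the effect at the first landmark and a unit-motivation contrast moves
from log HR −0.42 at s = 1 to −0.40 at s = 2 under the default
coefficients. A `landmark_coding = "s"` option codes the raw index instead;
the two parameterizations describe the same model with β1 shifted by β2.

**Estimation.** Newton–Raphson with step-halving on the pooled partial
likelihood; convergence at score max-norm ≤ 1e-8, at most 100 iterations.
Breslow tie handling by default (Efron available); ties are common because
event days are integers. The cumulative baseline hazard is the Breslow
step-function estimator. All design columns are centered at a fixed
reference subject (23 y, 1.80 m, 80 kg, 14% body fat, 2.8 km Cooper, 55
push-ups, 55 sit-ups, education "unknown", 5 on every Likert item, no
pain), whose linear predictor is therefore exactly 0 at every landmark and
who owns the reported baseline hazard. Variance is model-based (inverse
observed information) by default — the nonoverlapping windows make each
recruit's window contributions conditionally independent — with a
recruit-clustered sandwich option. A Rubin's-rules pooling utility is
provided for multiply imputed fits; the pipeline default is single
imputation (m = 1), for which pooling is the identity.

**Conditional dropout probability.** For a subject at risk at landmark s
with covariates held at their landmark-s values,
P(dropout by week s+h) = 1 − exp(−[H0(7(s+h)) − H0(7s)]·exp(LP(s))).

## Preprocessing

* Missing continuous baseline measurements are filled by single mean
  imputation (observed-sample column means); education is categorical with
  an explicit "unknown" level and is never imputed.
* Weekly pain reports (location marks with an NPRS 0–10 severity) are
  dichotomized: 1 if any location was marked that week. The indicator is
  then retained over time; by default the carry is absorbing
  (ever-injured), with a `pain_carry = "locf"` switch for plain
  last-observation-carried-forward.
* Gaps in the weekly Likert items are completed by LOCF; weeks before a
  recruit's first observation stay unavailable, the recruit enters the risk
  sets only from that entry week (left truncation), and recruits who drop
  out before any observation are excluded.
* Items with a pre-LOCF missing fraction above 0.5 or observed variance
  below 1e-3 are screened out (strict inequalities). Under the default
  missingness configuration this removes the mental-fitness item, which is
  61% missing (not at random) and near-ceiling.

## Discrimination and validation

The incident/dynamic AUC(t) is the probability that a recruit dropping out
around day t carries a higher linear predictor than a recruit still in
training beyond t. Cases are events within ±7 days of t (the two-week
smoothing window), scored at their last at-risk landmark; controls are
recruits in training beyond t+7, scored at the last landmark at or before
t; tied scores count one half. No inverse-probability-of-censoring
weighting is used: horizons are one week and censoring is administrative.
Events in the first week precede every landmark and are not scorable, so
evaluation starts at day 7. Operating thresholds maximize Youden's J
(sensitivity + specificity − 1), ties broken toward higher specificity.

Validation is repeated stratified 10-fold cross-validation. Folds split
*recruits*, never stacked rows, so no recruit's landmarks appear on both
sides of a split; held-out recruits are scored by a model never trained on
them, and AUC(t) curves are aggregated over repeats with percentile bands.
The added value of the weekly information is quantified against a
conventional Cox model on the 9 baseline covariates alone (time from day
0, no landmarking), evaluated on identical case/control sets.

## The synthetic cohort generator

The real training records are not publicly deposited, so a generator
reproduces the statistical structure the analysis assumes; every estimate
in this package is computed on synthetic cohorts, and published estimates
serve only as calibration defaults and plausibility bands.

* **Baseline.** Independent truncated normals per covariate with the
  published means/SDs as targets and the eligibility limits as truncation
  bounds (height ≥ 1.65 m, mass ≥ 65 kg, Cooper ≥ 2.7 km, ≥ 30 push-ups
  and sit-ups, age 17.5–27.9 y). The pre-truncation location is solved by
  root finding so the *realized* mean matches the target. The published
  Cooper SD (1.58 km) is large relative to the 0.17 km gap between the
  mean and the 2.7 km floor, so the mean-matched distribution degenerates
  to an exponential-like tail above the floor and the realized SD is far
  smaller than printed; matching the mean was preferred. Education is
  drawn from (25%, 17%, 58%) for (level 1, level 2, unknown).
* **Weekly self-reports.** Per recruit and item, a latent recruit-level
  intercept (items centred near 7.5 on the 10-point scale; the
  mental-fitness item near-ceiling at 9.3 with SD 0.3) plus a stationary
  AR(1) deviation (autoregression 0.7, innovation SD 1), rounded and
  clamped to 1..10. Pain reports are weekly Bernoulli draws (probability
  0.015) with a uniform 1–10 NPRS when present — deliberately rare, as the
  source cohort reported remarkably few.
* **Dropout.** Weekly dropout probability 1 − exp(−h_w) with
  h_w = base_w · exp(LP_i(w)); the linear predictor is exactly the
  supermodel's, using the week-(w−1) observed status (week 1 uses baseline
  terms only, as no week-0 survey exists) and the published log hazard
  ratios as true effects. The day within the dropout week is drawn from
  the truncated-exponential law of a constant within-week hazard rather
  than uniformly: a uniform day makes the within-window event order carry
  no hazard information and measurably biases the partial-likelihood
  estimates at the calibrated hazard level, whereas the
  truncated-exponential draw makes the generated process exactly the
  proportional-hazards process the estimator assumes. Completers are
  censored at day 168. A truth table records every recruit's weekly linear
  predictor, hazard and dropout probability for oracle checks.
* **Base-hazard calibration.** The weekly base hazard is geometric,
  base_w = a·r^(w−1); (a, r) were solved once by nested root finding on
  the expected-dropout equations — 54.8% total dropout and 22% of dropouts
  within the first four weeks, evaluated analytically on 40,000 simulated
  covariate paths — giving a = 0.0641584, r = 1.01853, which ship as the
  defaults (`analysis/01_calibrate_generator.py` re-derives them).
* **Dropout reasons and exit surveys.** Reasons follow the published
  mixture 137:240:27 (injury, individual request, other; the counts sum to
  404 of 408 dropouts, so the mixture is normalized). Injury is up-weighted
  (×3) for recruits with a pain report, with the complementary weight
  solved so the marginal mixture is preserved. Dropouts receive a
  five-item exit survey (missing with probability 0.25) whose item means
  are tied to the true reason, so the "response ≥ 7" agreement rule is
  informative.
* **Missingness.** Matching the observed-data patterns: 8% of recruits
  lose at least one continuous baseline field; 4% are left-truncated by
  1–3 weeks; up to 1.4% of the cohort — chosen among *natural* week-1
  dropouts so outcomes stay intact — lose all status rows; recruits skip
  whole weekly surveys with probability 0.05 (weeks ≥ 2), giving LOCF real
  gaps to fill; and the mental-fitness item is erased not-at-random with
  probability logistic in (10 − latent value), the intercept solved so the
  overall missing share is 0.61.
* **Reproducibility.** All randomness flows from one seed through named
  independent streams (baseline, trajectories, dropout, missingness), so
  adding a stream never perturbs the others and a fixed seed reproduces a
  cohort byte-identically.

## What the synthetic cohorts do and do not show

The generator matches the study's marginals (baseline table, dropout rate
and timing, reason mixture, missingness patterns) and its hazard model is
exactly the supermodel — so parameter-recovery, coverage, oracle and
discrimination tests certify the *estimator and pipeline*, not the
published effect sizes. Real data differ in ways the generator does not
emulate: correlated baseline covariates (an optional correlation matrix
defaults to identity), non-proportional or nonlinear effects,
informative (non-administrative) censoring, and self-report behaviour that
no AR(1) captures. Published AUCs are therefore plausibility bands here,
not reproduction targets; on default synthetic cohorts the supermodel's
AUC(t) lands in the high 0.6s to low 0.8s over weeks 1–12, declining with
time as in the source analysis, and cross-validation shows a small
positive optimism.

## Numerical choices and edge cases

* Events exactly at a window boundary day 7s belong to (7(s−1), 7s].
* A recruit-landmark row exists only if LOCF can supply every retained
  item; with survey-level (row) gaps this makes the stacked row count
  exactly Σ_i (last landmark at risk − entry week + 1).
* Monotone-likelihood toy instances (no finite MLE) raise a convergence
  error rather than returning a boundary estimate; collinear or constant
  design columns raise immediately with the offending column named.
* AUC at a day with no scorable cases or controls is reported as missing
  (NaN), not an exception; cross-validation redraws a repeat's folds if a
  training split contains no events.
* Parameter-recovery suites run on missingness-free cohorts: LOCF is
  biased by construction whenever the truth moves during a gap, and the
  recovery criterion targets the estimator, not the imputation.

## Problem sizes used by the test and acceptance suites

Calibration checks average 20 cohorts of 744 recruits; baseline-generator
checks use 10,000 draws; parameter recovery and CI coverage use 50 cohorts
of 1,000; the supermodel-vs-baseline comparison uses 10 cohorts of 2,000;
cross-validation checks use 10 folds × 20 repeats on one 744-recruit
cohort (the 500-repeat production setting is a config value). These sizes
give Monte-Carlo errors comfortably inside the asserted tolerances while
keeping the full suite to a few minutes on one CPU.
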