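# Methods

`abpauto` implements a reproducible pipeline for a clinical question:
do office orthostatic blood-pressure measurements and 24-h ambulatory
blood-pressure monitoring (ABPM) abnormalities predict autonomic
dysfunction as established by a formal autonomic reflex screen?  The
package provides the feature detectors, the dysfunction scoring, the
association statistics, and a synthetic-cohort generator that makes the
whole chain testable without patient data.

## Classifiers

All thresholds live in `FeatureConfig`; defaults below are the standard
clinical definitions.

**Orthostatic hypotension (OH).**  A sustained fall of SBP >= 20 mmHg or
DBP >= 10 mmHg within 3 min of standing versus the supine/sitting
position.  "Sustained ... based on multiple measurements" is
operationalized on the *means*: the fall is mean supine/sitting pressure
minus mean of all standing readings taken <= 3 min after standing, with
both thresholds inclusive.  Per-standing-reading flags are also reported
so stricter aggregation rules can be applied downstream.  `delta_oh` is
the systolic component of that fall in mmHg.

**Reversal of circadian pattern.**  Nocturnal mean BP *equal to or above*
daytime mean BP (inclusive on equality).  Night is the half-open interval
[sleep, wake) taken from the patient journal; when the journal lacks
sleep/wake events a default 22:00-06:00 clock window is used with a
warning.  The BP component is configurable (systolic, diastolic, or
MAP = (SBP + 2 DBP)/3); the default is systolic, consistent with every
other rule in the battery being SBP-anchored.  Each segment must contain
at least 3 readings.

**Postprandial hypotension (PPH).**  An SBP fall >= 20 mmHg within 75 min
of eating.  Per meal: baseline is the last reading at or up to 60 min
before the meal (a cap that prevents stale baselines; configurable); the
drop is baseline SBP minus the minimum SBP over the half-open window
(meal, meal + 75 min].  A meal with no baseline or no post-meal reading
is unevaluable and the subject's flag is decided on the remaining meals;
a subject with *no* evaluable meal is unevaluable (distinct from
PPH-negative — a flag decided on zero meals would not be a measurement).

**Non-compensatory heart-rate response** (called "heart rate variability"
in this clinical context).  Over adjacent reading pairs: condition 1
triggers when SBP falls by strictly more than 20 mmHg and fails when the
HR rise is < 10 beats/min; condition 2 triggers when DBP falls by
strictly more than 10 mmHg and fails when HR does not rise.  "No rise"
for condition 2 is operationalized as a rise < 1 beat/min — the clinical
definition prints a number only for condition 1, so this is a stated
convention of the package, configurable.  Episode granularity is the
adjacent reading pair (no rolling baseline): it is the simplest rule
consistent with "when pressure decreased" and is deterministic at the
15/30-min cuff cadence.  A trace with no triggering pair is normal.

`abp_total` (0-3) counts the abnormal trace-level components
(reversal + PPH + HRV).

Boundary semantics are fixed and tested: drop = 20 mmHg is PPH-positive;
night mean = day mean is reversal-positive; an SBP fall of exactly
20 mmHg does **not** trigger condition 1.

## CASS scoring

The Composite Autonomic Scoring System sums sudomotor (0-3), cardiovagal
(0-3) and adrenergic (0-4) deficits on a 10-point scale; zero means no
dysfunction and any score of 1-10 is dichotomized as autonomic
dysfunction.  Subscores are taken as integers (the scale is defined in
points; half-points are rejected).  Computing subscores from raw
autonomic tests (Valsalva, tilt, sweat testing) is out of scope —
subscores are inputs.

## Statistics

* **Correlation screening**: Pearson product-moment r (equal to the phi
  coefficient for two binary variables) with the t-transform p-value at
  n-2 df; Spearman rho on tie-aware midranks as a per-pair override.
  The pipeline defaults to Pearson because the original screening used it
  for most pairs without listing the non-normal variables.
* **2x2 odds ratio**: OR = ad/bc with a Wald 95% CI on the log scale,
  exp(log OR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d)); the Haldane-Anscombe
  0.5 correction is added to every cell when any cell is zero (flagged).
  The p-value is a Pearson chi-squared test, switching to Fisher's exact
  test when any expected count is below 5.
* **Adjusted model**: maximum-likelihood logistic regression (Newton
  iterations, tolerance 1e-8 on the coefficient change, max 100
  iterations) with Wald standard errors; per-covariate OR = exp(coef).
  Complete/quasi-complete separation is detected (coefficient magnitude
  > 15 on the log-odds scale, or a singular information matrix) and
  raised as an error rather than reported as a huge OR.  The default
  covariate set is {neurological disorder, diabetes, OH, reversal, PPH,
  HRV}; neurological disease is coded as one flag (a config switch allows
  a different set).
* **ROC/AUC**: the tie-aware rank (Mann-Whitney) estimator with
  midranks — ties between a positive and a negative count one half, so a
  binary predictor's AUC is exactly (sensitivity + specificity)/2.  The
  95% CI uses the Hanley-McNeil variance (Q1 = A/(2-A),
  Q2 = 2A²/(1+A)), clipped to [0, 1]; the p-value is a two-sided normal
  test of AUC against 0.5 with the same variance.  Hanley-McNeil was
  chosen over DeLong for its deterministic closed form, adequate at
  n ≈ 100; DeLong is noted as a possible alternative.
* **Group comparisons**: Welch t (robust default; pooled-variance t is
  not offered) or Wilcoxon rank-sum for continuous variables;
  chi-squared/Fisher for dichotomous ones.  All tests are two-sided at
  0.05.  No multiple-testing correction is applied, mirroring the
  univariate screening design this package reproduces — a faithful but
  liberal choice.

Missing-data policy is pairwise-complete: each statistic uses the
subjects complete for its own variables and reports its n.

## Synthetic data

`simulate_trace` emulates the recording protocol (15-min cadence awake,
30-min asleep, journal sleep/wake/meal events) and plants
threshold-relevant structure only; it does not attempt realistic
continuous hemodynamics.

* **Circadian level**: day SBP baseline 135 mmHg (DBP 80), night offset
  -14 mmHg for a normal dipper and +6 mmHg to plant reversal.  The
  offset is applied with a 3-reading ramp at the sleep and wake
  transitions, because an instantaneous 14-mmHg step would itself look
  like an acute BP fall to the adjacent-pair HR detector.
* **Meal dips**: a transient SBP fall of `pph_drop` (30 mmHg when PPH is
  planted) lasting up to 60 min post-meal, recovering before the next
  meal's baseline window.
* **Stress dip**: one 35-mmHg transient dip at 16:00 (outside every
  post-meal window) present in every trace.  It guarantees that a
  >20-mmHg adjacent-pair SBP fall exists for every subject, so the
  non-compensatory flag is controlled purely by `compensation_gain`:
  HR rises by gain x (transient fall), 0.5 bpm/mmHg for a compensated
  subject (rise 17.5 bpm) and 0.1 for a non-compensatory one (3.5 bpm).
  Without it the HRV flag could not be planted independently of PPH.
* **Noise**: independent Gaussian per reading; `noise_sd` is the systolic
  sd, with diastolic and HR noise at half of it (the ~2:1
  systolic-to-diastolic variability of real ABPM).  All values are
  rounded to integers as a cuff device reports them.  Planted margins are
  >= 5 mmHg (or 5 bpm) beyond every threshold; at sd = 4 mmHg per-flag
  round-trip agreement stays >= 95%, and at sd = 0 recovery is exact.
* **Office readings**: two supine readings at 152/84 and standing
  readings at 1 and 3 min — 115/61 when OH is planted (fall 37/23,
  matching the cohort means the study reports) and 147/81 otherwise
  (fall 5/3).

`simulate_cohort` draws latent dysfunction at prevalence 0.808, each
feature flag at conditional prevalences P(feature | dysfunction) and
P(feature | none), covariates at the study's marginal rates (age 71 ± 9,
56.4% male, and the printed comorbidity rates), and a CASS total of
1 + Poisson(1.35) capped at 10 given dysfunction (zero otherwise, so
dysfunction <=> total >= 1 by construction), split into subscores by a
multivariate hypergeometric draw over the (3, 3, 4) capacities.
Conditional prevalences are the primitive parameters; the odds ratio is
derived, and `FeatureSpec.from_marginal_or` solves for the pair that
reproduces a requested marginal prevalence and OR (raising a
specification error when no probability pair in [0, 1] exists).  Default
features reproduce the study's marginals and ORs: reversal 81.9% / OR
2.32, PPH 75.5% / OR 4.83, HRV 60.6% / OR 3.75, OH 77.6% / OR 1.

Randomness: one root seed; per-subject trace/office seeds are drawn from
the root stream, so any subject's raw data can be rebuilt independently
(`materialize_subject`) and every output is a pure function of
(spec, seed).

What passing tests show — and do not.  The generator plants exactly the
structure the detectors measure, with clean margins; real recordings have
autocorrelated noise, irregular cadence, missed cuff inflations, and
abnormalities that do not come with 5-mmHg margins.  Round-trip recovery
therefore validates the *logic* of the detectors and pipeline, not their
clinical sensitivity/specificity.

## Problem sizes

The test suite and the acceptance script use: 500 subjects for
round-trip checks (noise 0 and 4 mmHg), 200 replicates of n = 5000 for
odds-ratio recovery (50 replicates in the script), n = 5000 null cohorts
for the chance-AUC band, and an end-to-end study at n = 94 — the size of
the cohort the design mirrors.  The full suite runs in well under a
minute on one CPU.

## Known limitations

* Initial and delayed OH variants are not modeled (cuff-interval data
  cannot resolve them).
* Beat-to-beat analysis, device binary formats, and CASS subscore
  derivation from raw autonomic tests are out of scope.
* Plausibility bounds for artifact rejection (SBP 60-260, DBP 30-150,
  HR 25-220, DBP < SBP) are a package convention — ABPM exports contain
  cuff artifacts but the handling is rarely reported — and are
  configurable.
* The generator's noise is independent across readings; autocorrelated
  noise would be a natural extension.
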