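# Methods

This note records the modelling choices behind `perimob`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic cohorts do and do not emulate, and the numerical
conventions that make the pipeline deterministic.

## The analysis window and normalization

Activity is analyzed on a surgery-anchored day grid spanning two years
before through two years after the operation. Day 0 is the surgery day and
belongs to the post-operative side; the simulator generates days −730 … 729
(1460 days), and ingestion keeps the closed interval ±730 days around the
declared surgery date.

"Baseline" is the **first year of the pre-operative window**, days −730 …
−366. Its arithmetic mean daily step count is each patient's normalization
constant, so one unit of normalized activity is "this patient's habitual
day". The median is available by configuration for users worried about
heavy-tailed days, but the mean is the default because the decline rule is
phrased in mean steps-per-day. The baseline standard deviation —
`baseline_sd`, the sample SD (ddof = 1) of the *raw, unsmoothed*
baseline-year daily counts — is stored alongside and is the unit of the
secondary-decline rule. Normalization requires at least 90 recorded
baseline-year days (default; configurable): below that the baseline mean
and SD are too noisy to anchor a per-patient rule.

Smoothing is a centered 14-day sliding mean over *recorded* days: missing
days shrink the window denominator and are never imputed, because a
recorded zero is information (a bed-bound day) while an absent day is
usually non-wear. Fourteen days is one activity-week cycle on each side of
the center and sets the time scale of everything downstream: dwell times,
boundary tolerances and derivative stability all inherit it. Edge windows
are truncated, so the global mean is preserved only up to an edge term of
order `window / n`.

## The six-epoch state machine

Segmentation walks the smoothed, normalized day grid with threshold
hysteresis. The tunable parameters, all in `SegmentationConfig`:

| parameter | default | units | role |
|---|---|---|---|
| `delta` | 0.10 | normalized activity | entry into pre-op decline: value < 1 − δ |
| `epsilon` | 0.05 | normalized activity | full recovery: value ≥ 1 − ε |
| `dwell_days` | 14 | days | minimum persistence of any state change |
| `decline_delta` | = `delta` | normalized activity | epoch-6 entry below the running epoch-5 level |
| `min_epoch5_days` | 14 | days | recovery must hold this long before a decline can follow |
| `min_epoch6_days` | 60 | days | minimum trailing evidence for a decline call |
| `refine_radius_days` | 45 | days | window of the local two-piece refit |
| `onset_refine_radius_days` | 150 | days | backward window for the decline-onset refit |

δ = 0.10 places the decline threshold one smoothed-noise standard
deviation below baseline under the default simulated conditions (daily
coefficient of variation ≈ 0.30, smoothed by √14), which is the largest
value that still detects moderate declines and the smallest that does not
chatter. ε = 0.05 is deliberately tighter: "commensurate to baseline"
should mean within 5%. The dwell of 14 days matches the smoothing window —
transitions shorter than the smoother's support are not resolvable and
should not switch states.

Raw threshold crossings are biased estimates of change days: on a ramp of
slope *r* the crossing lags the true kink by δ/r, which for shallow
pre-operative declines is weeks. Each detected boundary is therefore
refined to the nearest shape feature of the smoothed curve:

* **decline onset** (epoch 1→2): a two-piece linear fit over a
  backward-looking window (150 days) whose breakpoint lands on the
  plateau-to-ramp kink;
* **spontaneous-recovery start** (2→3): monotone walk back to the local
  minimum;
* **spontaneous-recovery end** (3→2): two-piece fit over a forward window —
  the fast fall rejoins the slow decline at a knee, not an extremum, and the
  true change day always lies downstream of the crossing;
* **recovery** (4→5): monotone walk forward to the plateau start;
* **secondary onset** (5→6): monotone walk back to the plateau end.

On noise-free piecewise-linear input every refined boundary lands within
the smoothing half-width (±7 days) of the generative change day. Under
noise the monotone walks stop at the first counter-movement, so noisy
boundaries revert toward the (biased) crossing day; duration features
remain monotone in the truth, which is what the classifiers use.

A trajectory that never leaves baseline is labeled {baseline year,
fully-recovered remainder} and flagged `never_left_baseline`; in this
degenerate case the "recovered" state extends into the pre-operative side,
which is the one deliberate exception to the rule that epochs 4–6 are
post-operative. A trajectory that never re-reaches 1 − ε post-operatively
has no epoch 5, is flagged `not_fully_recovered`, and can never be a
decliner.

Epoch-6 entry has two guards beyond the level test: the drop must persist
(the mean from onset to the end of the record must itself sit below the
running plateau level by `decline_delta`) and there must be at least
`min_epoch6_days` of trailing data. Both exist to stop transient noise
excursions from being called a terminal functional decline; both were
chosen from the statistics of the level test (a 14-day excursion one
threshold deep, averaged over a 60-day window, contributes well under the
outcome threshold).

## The 0.25-SD secondary-decline rule

The outcome is a raw-scale statement: the patient declined when mean
steps-per-day in a trailing 60-day candidate window inside epoch 6 is at
least `0.25 × baseline_sd` below the epoch-5 mean. The comparison is
**inclusive** (exactly 0.25 declines) and monotone in the threshold by
construction. The depth is reported in SD units; when the baseline SD is
exactly zero (constant noise-free input) any positive drop is reported as
infinite depth. The reference SD is the baseline-year SD, not the
recovered-epoch SD — the baseline year is the patient's pre-morbid
variability and is available for every patient with a valid normalization;
the alternative is one configuration switch away in spirit but was not
implemented because no test could distinguish them on the available
evidence.

## The synthetic cohort

The generator inverts the epoch structure: a piecewise-linear expected
curve (flat baseline → linear decline to a nadir at surgery, optionally
interrupted by a trapezoidal spontaneous-recovery bump → linear recovery to
a plateau → optional late decline ramping to a sustained deficit), with
negative-binomial daily counts (variance µ(1 + αµ)) and
missing-completely-at-random day drops. Weekly periodicity is available
(`weekly_amplitude`) but off by default. Cohort defaults, chosen once as
the study conditions:

* decline prevalence 0.347; baseline mean uniform on 3000–9000 steps/day;
* dispersion α = 0.09, i.e. a daily CV near 0.30 — strongly overdispersed
  relative to Poisson (variance-to-mean ratio in the hundreds), in the
  range reported for consumer step counts;
* missing 5–20% of days; decline onset uniform on −420 … −140 days with a
  nadir at 35–65% of baseline, giving a mean acute pre-operative decline of
  roughly 250 days;
* spontaneous-recovery bumps in 40% of patients, 60–110 days long, placed
  only after the decline has passed 0.85 of baseline (recoveries follow
  meaningful declines), flat-topped because remissions last weeks;
* recovery length normal (240 ± 50 days) for non-decliners and
  (240 − `recovery_gap_days`) ± 40 for decliners, with
  `recovery_gap_days` = 120 by default — this *planted* dependence between
  fast recovery and later decline is the signal the classifiers are
  benchmarked on, and the knob the parameter-recovery experiments sweep;
* plateau normal (1.00 ± 0.053), so roughly one patient in six never
  re-reaches 95% of baseline and is generatively unrecoverable; decliner
  plateaus are truncated at 0.96 because a secondary decline presupposes
  recovery;
* secondary declines start 120–360 days after recovery completes (capped
  at day 560 so the window retains evidence), 0.5–1.5 baseline SDs deep,
  ramping over 30 days.

Ground truth records the generative interval structure, and the decline
label is `depth_sd ≥ 0.25` exactly. Per-patient randomness comes from
children of one master `SeedSequence` (one spawn per patient, split into
parameter/covariate/trajectory streams), so cohorts are reproducible
patient-by-patient and extending a cohort never changes existing patients.

Two presets define the favourable regimes used by the recovery
experiments: `low_noise` (α = 0.05, 3–7% missing, decline depths 1–2 SD)
and `noise_free` (α = 0, no missing days; the counts are the rounded
expected curve). In the noise-free limit the daily SD degenerates to the
Poisson scale √µ, so that preset expresses decline depths in larger nominal
SD units (18–28) to keep the injected drops at a visible 0.2–0.4 of
baseline; the unit is degenerate there, the geometry is what the
segmentation-recovery experiment needs.

Covariates are drawn from binned marginals typical of a lumbar-surgery
cohort (ages concentrated in the seventh decade with mean ≈ 61 years, BMI
centred near 28, fusion : decompression : other ≈ 34 : 28 : 13, mostly 1–3
operated levels). Covariates are independent of the trajectory by default —
age and BMI are noise features, which is itself useful: a classifier that
ranks them above the planted activity signal is overfitting.

What the generator does **not** emulate: intraday structure, device error,
autocorrelated behavioural noise (days are conditionally independent given
the curve), informative missingness (gaps are MCAR), re-recovery after a
secondary decline (declines are terminal within the window), and any real
dependence of outcome on covariates. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
clinical performance on real exports — in particular, real series with
strong weekly routines or wear gaps correlated with illness will degrade
boundary localization in ways these tests do not measure.

## Features and leakage

Per epoch: cumulative duration (days), 1st derivative (OLS slope of
smoothed activity vs day over the epoch's merged intervals — robust to
missing days, unlike endpoint differences), 2nd derivative (OLS slope of
the day-to-day finite differences, which recovers 2a exactly on a
noise-free quadratic at²), and a presence indicator; missing epochs are
zeros + indicator so the table stays rectangular. Epochs shorter than
three recorded days yield zeros.

The label is defined on epochs 5–6, so feeding those epochs to the
classifier is circular. The default `pre_recovery` policy admits epochs
1–4 only; `with_recovery` adds epoch 5 for users who want the full
activity-parameter set; epoch 6 is refused under every policy and an
assertion enforces it. Both policies exist because the honest-prediction
and faithful-replication use cases are both legitimate; the default is the
honest one.

## Classifiers and evaluation

Logistic regression is standardized + L2 (C = 1, scikit-learn); the random
forest uses 500 trees; gradient boosting uses depth-3 trees, 100 rounds,
learning rate 0.1 (xgboost). These are unremarkable defaults for a
low-dimensional tabular problem, exposed as `hyperparams` per call; no
search is performed. Evaluation is a single stratified 4:1 split
(stratification is essential at n ≈ 75 with ≈ 35% positives; an
unstratified 15-patient fold is frequently degenerate), a 0.5 posterior
threshold for the confusion matrix, and metrics that report `None` — never
0 — when a denominator is empty. No class reweighting is applied. The
AUROC is computed from the empirical ROC curve, whose trapezoidal area
equals the tie-half-credited Mann–Whitney probability exactly; tests
verify this against exhaustive pair enumeration. Zero-variance features
are dropped with a warning before fitting.

`compare_groups` (one-way ANOVA, two-sample or paired t) exists for cohort
description — e.g. epoch durations by surgery type — not for inference
claims.

## Numerical conventions

* Day 0 belongs to the post-operative side; window boundaries are closed.
* Duplicate dates in a CSV export merge by summation; negative or
  non-numeric steps and unparsable dates are hard errors naming the row.
* Flat-vs-ramp decisions in the boundary walks use a 1e-9 slope tolerance;
  rounding of noise-free counts injects quantization an order of magnitude
  above machine epsilon but well below it in normalized units.
* All randomness flows from explicit seeds or `SeedSequence` spawns; the
  segmentation and feature stages are deterministic functions of their
  inputs and configuration.
* The experiment scales (100 noise-free trajectories for boundary
  recovery, 500 patients for label recovery, 400 for the classifier
  benchmarks, 20 permutation replicates) were chosen so the binomial or
  rank-statistic error of each check is several times smaller than the
  margin being asserted.

## Known limitations

* Boundary localization under noise inherits the crossing bias wherever
  the monotone-walk refinement stops early; epoch durations are
  consistently ordered but not unbiased.
* The recovery detector is permissive near the threshold: a plateau just
  below 1 − ε can be pushed over it by noise for one dwell period, so the
  detected fully-recovered fraction overstates the generative one at high
  dispersion.
* The decline rule's trailing-window minimum is an upward-biased depth
  estimator under noise (a maximum over correlated window deficits); the
  epoch-6 entry guards, not the depth estimate, carry the false-positive
  control.
* Calendar effects (time zones, DST, season) are out of scope; dates are
  treated as plain days.
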