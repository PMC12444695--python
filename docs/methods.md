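# Methods

This note documents the models and procedures implemented in
`bedmotion`, the parameter choices behind them, what the synthetic-data
generator does and does not emulate, and the numerical decisions a
maintainer should know about.

## Sensor model and event detection

The monitored signal is the tilt of a hospital mattress, sampled at a
nominal 1 Hz on two axes: `angle` (X-axis) and `pitch` (Y-axis), both in
degrees and physically bounded to [−90°, 90°]. Acceleration is carried
in units of g; at rest the magnitude ‖a‖ = √(aₓ²+a_y²+a_z²) sits near
1 g (gravity). Timestamps are elapsed seconds from recording start;
sampling gaps are preserved, never interpolated.

A repositioning event is a *sustained, simultaneous* excursion of both
tilt axes. The detector keeps a baseline at the last registered
position (initially the first sample). A candidate opens at the first
sample whose deviations exceed **both** thresholds — strictly greater
than 2.0° each — and is confirmed at the first sample at least the
dwell (10 s of elapsed time) after onset, provided every sample in
between also exceeded both thresholds. On confirmation the baseline
resets to the confirming sample's values; on any drop below either
threshold the candidate is discarded and scanning resumes at the
failing sample with the old baseline.

Design choices worth stating:

- **Baseline-reset, not sample-to-sample differencing.** At 1 Hz a slow
  roll never produces a 2° difference between consecutive samples;
  tracking deviation from the last registered position detects slow and
  fast repositioning alike. This is the only supported mode.
- **Event time = onset.** The movement physically occurs when the tilt
  starts changing; the confirmation time (onset + dwell) is retained on
  each event for audit.
- **Strict inequalities** at both thresholds: a deviation of exactly
  2.0° does not count.
- **Gaps and the dwell.** The dwell is measured in elapsed time, so a
  sampling gap inside a candidate window confirms the event if the
  samples on both sides of the gap stay above threshold. A strict mode
  (`DetectorConfig.max_gap`, default off) instead discards candidates
  containing gaps longer than 2 s.
- The dwell requires the stream to *reach* onset + dwell: events cut
  off by the end of a recording are never emitted.

Derived statistics: movement rate = event count / recorded hours;
motion intensity = per-sample ‖a‖ reduced to per-10-minute-window
maxima over half-open windows [k·600 s, (k+1)·600 s), with the trailing
partial window included by default (a flag excludes it), the mean of
those maxima, and the overall maximum. Event counts are binned into
half-open 60-s bins for the validation analysis; an onset at exactly the
recording end is assigned to the final bin so counts are conserved.

## Cleaning

Two cleaning steps precede all analysis:

1. **Discharge-tail truncation.** When the sensor keeps logging after
   the patient is discharged, the tail of the recording shows zero
   variability in both tilt axes. The maximal terminal run in which
   every rolling 300-s window has standard deviation < 0.01° in *both*
   angle and pitch is removed, provided the run spans ≥ 30 minutes.
   The window, threshold, and minimum-tail parameters are exposed; the
   defaults are chosen so ordinary sensor jitter (≈ 0.1° SD) can never
   trigger truncation while any genuinely empty bed does. The
   operation is idempotent.
2. **Short-recording exclusion.** Recordings spanning strictly less
   than 1 hour (after truncation) are excluded from cohort analysis; a
   recording of exactly 1 hour is kept.

## Immobility alerting

Repositioning protocols call for turning at-risk patients at least
every 4 hours, so the alert simulation partitions each recording into
maximal movement-free intervals delimited by recording start, every
event onset, and recording end. Each interval of length ≥ 14 400 s
yields exactly one alert, triggered at interval start + threshold; a
further alert requires an intervening movement followed by another
qualifying interval. The immobility clock starts at recording start —
a patient who never moves alerts once, 4 h in.

The heat-map matrix reports, per patient and per 15-minute block, the
mean of time-since-last-movement over the integer seconds in
[k·900, min((k+1)·900, duration)). With a single movement at t = 0 the
block-k mean has the closed form k·900 + 449.5 s (mean of an arithmetic
sequence), which the tests verify to 1e−9. Blocks past a patient's
recording end are missing values; the rendered heat map marks alert
positions with asterisks, but the CSV matrix is the canonical artifact.

## Video cross-validation

The validation arm films subjects while the sensor records. The
toolkit deliberately consumes *landmark coordinate series* (both
shoulders, both hips, nose; x and y in units of frame width) rather
than video, so no pose-estimation stack is required: the contribution
being tested is the event logic, not pose estimation. The body's
center of mass is the unweighted mean of the five landmarks (frames
missing any landmark are skipped and counted). The video detector
mirrors the sensor rule: Euclidean center-of-mass displacement from a
baseline > 2.5 % of frame width, sustained for 15 consecutive valid
frames, with baseline reset on confirmation; onsets convert to seconds
via the frame rate.

Agreement is Pearson's r between the two modalities' 60-s binned counts
per subject (undefined — reported as NaN, never 0 — if either series
has zero variance). Across subjects, each r is mapped to z = atanh r;
the report is tanh(z̄) with a 95 % CI tanh(z̄ ± 1.96·sd(z)/√k). With
k = 3 subjects this normal-quantile CI is fragile, so an
inverse-variance pooling alternative (per-subject SE 1/√(n−3)) is
available when bin counts are supplied. Perfect agreement (|r| = 1,
common on short synthetic runs) has infinite z and is rejected unless
the explicit `clamp` option is used, which clips to 1 − 1e−7.

## Cohort statistics

- **Median split.** The threshold is the cohort median movement rate;
  rates strictly above/below go high/low, and values tied with the
  median are assigned one at a time to the smaller group (low on a size
  tie), guaranteeing group sizes differ by ≤ 1 — with 44 distinct rates
  this yields 22/22.
- **Group comparisons.** Continuous variables use the unpaired Welch
  t-test (the pooled-variance form is available via `equal_var=True`;
  Welch is the default because equal variances are rarely defensible in
  small clinical cohorts). Categorical variables use a two-sided
  Fisher exact test. Because the admitting-service variable can have
  more than two levels, the 2×k exact test is implemented here by full
  enumeration of tables with the observed margins (p = total
  probability of tables no more probable than the observed, with a
  1e−9 relative tolerance on the probability comparison); it reduces to
  the classic 2×2 test and is cross-checked against scipy there.
  Degenerate variables are skipped with a note, never silently dropped.
- **Normality gating.** Shapiro–Wilk (3 ≤ n ≤ 5000) decides whether
  rank-based correlation is reported; the cohort pipeline reports
  Spearman throughout since most mobility metrics are skewed.
- **Spearman with permutation inference.** ρ is the product-moment
  correlation of average ranks. The null is built by permuting one
  variable (default 10 000 iterations, vectorised); the two-tailed p is
  the plain proportion of permuted |ρ*| ≥ |ρ| (a `conservative` flag
  adds the +1/+1 correction). A 1e−12 slack guards the ≥ comparison
  against floating-point noise in tied-rank arithmetic.
- **Bootstrap CI.** Pairs are resampled with replacement (default
  1 000 resamples); the 2.5th and 97.5th percentiles of the ρ
  distribution form the interval. Resamples in which either variable
  collapses to a constant are skipped and logged.
- **Clustering.** Features (movement rate, mean and max intensity, and
  the per-patient mean and SD of each tilt axis — the per-patient
  summary of "angle" and "pitch" chosen here, configurable by passing a
  different feature frame) are z-scored; constant features are dropped
  with a warning. K-means runs with 10 restarts under a fixed seed for
  each candidate k in 2..8; the k with the highest mean silhouette
  score wins, ties to the smallest k. Labels are 1-based. PCA is the
  centered 2-component projection; rank-deficient inputs report an
  explained-variance fraction of 0 for absent components.
- **No multiple-testing correction** is applied anywhere; results
  tables carry raw p-values.

All stochastic routines take explicit integer seeds; child seeds are
spawned below 2³¹.

## Synthetic data: what it emulates, what it does not

`StreamSpec` generates a 1 Hz stream as a piecewise-constant level on
each tilt axis plus Gaussian jitter. Defaults describe a typical
monitored stay and are fixed once: 10 h duration, 10 events/h, 5° steps
on both axes (sign-bounded so levels stay within ±30°), 0.1° noise SD,
5 sub-dwell transients/h (3 s duration, same 5° amplitude — a correct
detector must reject every one), acceleration resting at 1 g on z with
0.5 g bursts at events. Event onsets are uniform with a minimum
separation of dwell + 5 s (via the uniform-spacing transform), keeping
the planted truth unambiguous; spikes are kept at least that far from
every event. An optional exactly-flat tail emulates the empty bed
after discharge.

`CohortSpec` draws 44 patients: age ~ N(63, 17²) clipped to [18, 100],
BMI lognormal (median 28.5, σ_log 0.18), comorbidity count
~ Poisson(8.8), Braden sub-scores weighted toward 3–4, service
categorical (medicine/cardiology/surgery). True movement rates are
lognormal with median 7.2 movements/h and σ_log 0.75 (range roughly
1.5–30 movements/h); BMI and rate share a Gaussian copula whose Pearson
parameter 2·sin(πρ_s/6) plants a Spearman correlation of ρ_s = 0.24
exactly at the population level. Recording durations are lognormal
(median 20 h, clipped to [1.5, 53] h). `gen_landmark_pair` drives the
landmark center of mass with 0.05-frame-width steps at the *same*
onsets as a sensor stream, with 0.003 jitter per landmark.

What the generator does **not** model — and therefore what passing
tests do not establish about real data:

- **No circadian structure.** Events are time-homogeneous, so 4-hour
  movement-free intervals are vanishingly rare at realistic rates and
  the simulated cohort produces essentially no alerts; in real cohorts
  alerts arise from overnight immobility. The alert engine itself is
  verified directly against an independent second-by-second oracle on
  random schedules instead.
- **Step-like events only**: no slow drifts, posture-dependent
  baselines, bed-exit artifacts, or heavy-tailed sensor noise; at the
  default noise level the sensor and video detectors recover the
  planted schedule exactly, so cross-modal agreement is ≈ 1 rather
  than the ≈ 0.9 typical of real recordings.
- Covariates other than BMI are independent of mobility by
  construction; group comparisons on synthetic cohorts are null cases.

## Problem sizes in the acceptance script

`scripts/acceptance.py` regenerates the study at the package's default
scale — 3 validation subjects at 2 h each, and a 44-patient cohort with
lognormal durations (median 20 h), every third patient carrying a 1-h
discharge tail to exercise truncation — and reruns the entire pipeline
from raw streams to clusters. These sizes mirror the defaults above
and complete in well under a minute.

## Known limitations

- The 2×k Fisher enumeration is exponential in k and intended for the
  small contingency tables of cohort comparisons (k ≤ ~6, n ≤ a few
  hundred).
- The Fisher-z CI with k = 2–3 subjects is wide and fragile by nature;
  prefer the inverse-variance pooling when per-subject bin counts are
  known.
- The permutation p-value has resolution 1/n_perm and can be exactly 0
  under the plain-proportion convention; use the `conservative` flag
  when a strictly positive p is required.
- Posture classification and bed-exit detection are out of scope: a
  patient out of bed looks immobile to the sensor.
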