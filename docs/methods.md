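# Methods

This note documents the models, conventions and numerical choices behind
`cohwear`, and what the synthetic-data experiments do and do not establish.

## Data model and calendar conventions

All streams live on a UTC time axis; input timestamps may carry any ISO-8601
offset and are converted on load. Days are UTC calendar days, half-open
`[00:00, 24:00)`, so a day is never split or duplicated by travel across
time zones. Gaps are absent rows, never sentinel values, which keeps every
windowed operator (median resampling, moving means, masks) a simple
computation over the present samples. Duplicate timestamps within one
(participant, device, channel) are rejected rather than averaged: a
duplicate almost always indicates an upstream merge error, and silently
averaging would hide it. Sub-minute data are reduced to minute resolution by
the in-minute median, which is robust to single-beat artifacts.

Travel-day exclusion (for circadian summaries) removes each annotated travel
day and the two following calendar days, enough for the acute phase of jet
lag at the day-level granularity of the summaries. Travel days are supplied
as annotations; inferring them from GPS or flight logs is out of scope.

## Resting-state extraction and personalized normalization

Activity dominates the variance of heart rate and skin temperature, so all
baseline statistics are computed on *resting* minutes only: step count
present and zero at the minute and at every present minute within a
10-minute lookback (including the current minute), and no labeled
walking/running/cycling/flight interval covering the minute. Minutes with
absent step data fail the mask — absence of evidence of stillness is not
treated as stillness. A 1-minute lookback mode mirrors the looser
cohort-profiling convention (only the current minute step-free).

Resting minutes are standardized per (stratum, device) cell, where the
stratum is the sleep/wake state from the device's sleep track (uncovered
minutes count as wake), or the hour of day (24 cells) for records without a
sleep track. Cell statistics are the mean and *sample* (n−1) standard
deviation over all masked minutes of the full monitoring period; sample SD
is the conventional default where only "standardization" is specified. Cells
need at least 500 resting minutes (about one week of nights for the sleep
stratum) or an insufficient-baseline error is raised; a zero-variance cell
raises a degenerate-baseline error rather than emitting infinities.

The baseline deliberately **includes** ill days: the method is meant to run
prospectively, where sick periods are unknown, and the statistic of interest
is deviation from the participant's overall norm. The cost is conservative:
with f the ill fraction of resting minutes and k the effect size in SD
units, a shift comes back attenuated by roughly a factor
`(1 − f)/sqrt(1 + f·k²)`. On a 600-day record with a single shifted day
this bias is ≤ 0.06 SD at k = 4 (the recovery experiments bound it
empirically); on very short, heavily ill records it matters, which is why
the pipeline-closure experiments use multi-month records. An exclusion flag
is not provided as a default because it would require the labels the
detector is supposed to find.

The **daily outlier fraction** is the share of a day's resting minutes with
z above 2, upper-sided by default because the illness signature of interest
is *elevated* HR and skin temperature; a two-sided mode is available.
Days with no resting minutes are absent rather than zero.

## The Change-of-Heart detector

The normalized resting-HR series is smoothed with a centered moving average
of 180 minutes (even spans are widened by one minute so the window is
symmetric). At the edges of a continuous stretch the window shrinks
symmetrically (the value at position i from an edge averages 2·min(i, h)+1
grid minutes); absent minutes inside a stretch are simply omitted from the
mean. Stretches separated by more than 180 minutes of missing data are
smoothed and peak-called independently — bridging long absences would
fabricate signal where none was recorded.

Peak calling on the smoothed signal:

* local maxima, with a flat maximal run resolved to its **leftmost** sample
  (a deterministic tie-break; run boundaries are never peaks);
* a peak's **prominence** is its height minus the larger of its two base
  levels, each base the minimum of the signal between the peak and the
  nearest strictly higher sample on that side (or the stretch boundary);
* peaks with height ≥ 2 and prominence ≥ 2 (z units) survive;
* the 180-minute minimum separation is enforced greedily in descending
  height order (equal heights in ascending time), discarding any candidate
  closer than the minimum to an already-kept peak.

These four defaults (span, height, prominence, distance = span) are the
method's frozen hyperparameters. The implementation is validated two ways:
exact agreement with a direct-definition brute-force oracle on a thousand
random series (including the constraint ordering: filter by height and
prominence first, then prune by distance), and exact agreement with
`scipy.signal.find_peaks` on plateau-free input with the distance constraint
disabled — scipy orders distance pruning *before* its prominence filter and
places plateau peaks at the run middle, so only that restricted comparison
is meaningful.

## Event windows and ROC evaluation

Positive windows are built from symptom spans and from blood tests with CRP
above the high band (10 mg/L by default; per-participant bands are
configurable), each extended three days earlier because the physiological
signal can precede the report; overlapping or adjacent extended spans merge
into maximal runs. Negative windows are either (a) windows centered on
normal-CRP measurement days (< 3 mg/L), clipped to the monitoring span and
to exclude positive days, or (b) the complement of the positive days tiled
into consecutive windows, keeping a final partial tile only when at least
half the nominal length; the default tile length is the median positive
window length, so positives and negatives have comparable exposure.

Each window receives a binary score (does a retained peak fall inside?) and
a continuous score (maximum smoothed z inside the window; −∞ and flagged if
the window has no data). Binary presence/absence alone yields a single
operating point, so the ROC sweeps the continuous score — the very quantity
the height threshold cuts — which makes the threshold-2 operating point
coincide with the binary rule. AUC is the trapezoidal area with simultaneous
steps on ties, computed via `sklearn.metrics.roc_curve`; it equals the
normalized Mann–Whitney U statistic, which the tests assert exactly. No
cross-validation is performed: the detector has no per-participant fitting
beyond the frozen defaults, and the evaluation unit is the window.

## Flight-stage SpO2 analyses

Stage boundaries are not standardized anywhere, so cruise is defined as the
period at or above 95% of the flight's maximum recorded altitude
(configurable); ascent runs from takeoff to the first such sample, descent
from the last such sample to landing. Altitude is joined to SpO2 by nearest
timestamp within 5 minutes — public altitude traces are sparse — and
samples without a nearby altitude reading are flagged unlabeled rather than
guessed. Saturation categories are ≥97, [91, 97) and <91 %: exhaustive and
disjoint for non-integer readings.

Adaptation tests restrict to samples above 35,000 ft so that altitude is
comparable across bins. Quarters mode splits the airborne span into four
equal time quarters and rank-sum-tests (two-sided Wilcoxon) the last quarter
against each other; time-bins mode compares samples >7 h after takeoff
against samples <2 h after takeoff with a two-sample Kolmogorov–Smirnov
test. Flights whose duration leaves a compared bin empty return an explicit
not-applicable result instead of a p-value. The tired-vs-alert SpO2
comparison is also a two-sample KS test. PVT sessions comprise 12 stimuli;
misses and responses slower than 500 ms are censored to 500 ms before the
mean, bounding the influence of lapses.

## Diurnal profiles, agreement, exposure

Hour-of-day summaries use the dataset's home timezone with a DST-aware
clock (each sample is bucketed by its local wall-clock hour on its local
date). The day/night capture windows are 3–4 p.m. local with strictly more
than 30 steps in the hour (guaranteeing wakeful activity) and 3–4 a.m. with
strictly fewer than 5 steps *and at least one step sample* (so missing data
cannot impersonate stillness). Steps per day is the mean per-second step
rate times 86,400 s. Bland–Altman agreement pairs samples by exact
timestamp match and reports the mean difference with mean ± 1.96·SD limits;
Pearson r on constant input is returned as a flagged `None` rather than a
propagated NaN. Radiation exposure is summarized as the mean elevated-window
rate over the background rate, rounded to one decimal.

## Synthetic-data generator

The generator produces what the analysis assumes and nothing more:

* minute-grid HR and skin temperature as stratum mean plus AR(1) noise with
  the stratum's marginal SD (sleep HR 69.2 ± 7.7 BPM, wake 84.5 ± 11.3;
  skin temperature 91.3 ± 2.0 / 86.6 ± 3.2 °F; sleep 22:00–06:00). The
  AR(1) autocorrelation is 0.8 per minute — strong enough that smoothing
  and peak behavior are non-trivial (a 3-h window mean has SD ≈ 0.22 z
  rather than the 0.07 of white noise);
* activity bouts per a daily schedule archetype (commuter default), during
  which HR moves to the activity mean (walking 101.1, cycling 114.1,
  running 145.2 BPM) and steps are positive; plus a 2-minute incidental
  stroll at the top of each waking hour (small +3 BPM elevation) so the
  daytime capture window has step evidence, as real records do;
* missingness by random minute deletion (5% default), shared across
  channels as for a single device;
* illness events add `effect × stratum SD` to resting minutes only, making
  recovery through the normalization exact by construction; overlapping
  events are rejected to keep the truth unambiguous;
* CRP is 0.2 mg/L at baseline, ramps linearly to the event peak over 24 h,
  decays exponentially (2-day time constant) after resolution, with
  log-normal noise (CV 0.1);
* flights have trapezoidal altitude (25-min climb/descent, shorter flights
  proportionally), SpO2 = ground level − drop·(altitude/cruise altitude)
  (5% at cruise by default) + a linear adaptation ramp after 7 h + Gaussian
  noise (0.8%), PVT response times rising linearly with the instantaneous
  SpO2 deficit, and tired/alert labels thresholded on the deficit plus
  noise.

Everything regenerates bit-identically from `(params, seed)`.

**What passing tests show** — that the pipeline's operators are correct
against independent oracles and that, under the stated generative
conditions, the detector recovers every injected event of ≥2.5 SD lasting
≥24 h with AUC > 0.9 against complement negatives. **What they do not
show** — performance on real wearable data, whose noise is neither Gaussian
nor stationary, whose sleep labels and activity annotations are imperfect,
and whose illnesses do not shift resting physiology by a clean constant.
The generator also omits circadian structure within strata, device drift,
and postural artifacts.

## Problem sizes and numerical choices

The pipeline-closure experiments use ten 600-day participants with three
events each (effects 2.5–4.7 SD, durations 24–120 h, placed in separated
thirds of the record so positives never merge); 600 days keeps the baseline
contamination of a single event below ~2% of resting minutes, which the
attenuation formula above shows is needed for shift recovery within 0.2 SD
at k = 4. The diurnal-recovery experiment uses one 30-day record; with the
stated AR(1) noise the capture-window estimator has an SD near 0.9 BPM at
that length, so the ±1 BPM recovery band is intrinsically tight — the
experiment is reported at a fixed seed. Null-calibration checks of the
adaptation test report the median p across five seeds, since any single
null p is uniform by construction. Peak pruning and plateau ties are fully
deterministic (descending height, then ascending time; leftmost plateau
sample), so repeated runs are byte-identical.

## Known limitations

* Baselines are global over the record: slow drift (fitness change,
  seasonality) inflates the SD and attenuates z-scores; no detrending is
  applied.
* The smoothing edge convention (symmetric shrinking window) is a declared
  choice; other reasonable edge rules shift peak times near record edges by
  up to half a span.
* Event windows are day-granular; sub-day onset timing is not evaluated.
* The quarter-based adaptation test compares quarters at a single altitude
  floor (35,000 ft) rather than matching altitude bin-by-bin.
* Cross-participant pooling, AUC confidence intervals and multiple-testing
  control are out of scope.
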