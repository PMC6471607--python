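# Methods

This note documents the models and procedures implemented in `chairrise`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish about real recordings.

## Sensor model and conventions

The primary stream is a hip-worn IMU sampled at 100 Hz: tri-axial
acceleration in m/s² (gravity-inclusive, so an upright sensor at rest reads
`acc_v ≈ +9.81`) and tri-axial angular velocity in deg/s, with axes fixed to
(vertical, mediolateral, anterior-posterior). A force plate sampled at
200 Hz under the subject's feet provides the reference ground reaction
force. Time is session-relative seconds; label segments are half-open
`[start, end)` intervals over the vocabulary
`{SIT, STAND, SIT_STAND, STAND_SIT, DYNAMIC, OTHER}`, stored maximally
merged. Files are plain CSV with `#`-prefixed metadata lines; floats are
written at full precision and parsed with round-trip precision so
read∘write is the identity.

When both streams are present they are cropped to their common interval;
a residual clock offset is estimated by normalized cross-correlation of the
*first differences* of the vertical acceleration and the (resampled)
vertical force. Differencing suppresses the sitting/standing baseline steps
in the force channel so the shared rise/descent pulses dominate; offsets
above 0.05 s are corrected by shifting the force time axis. The operation is
idempotent.

## Preprocessing

Filtering is a zero-phase (forward–backward) 4th-order Butterworth low-pass.
The filter family and order are the package's choice: zero phase keeps
transition timestamps unbiased, which matters more here than the exact
roll-off. Window sample counts round half-up (`1.135 s · 100 Hz → 114`
samples); the step is at least one sample, and the *realized* grid step
(`step_n / fs`) — not the nominal seconds value — is used whenever window
indices are mapped back to time, otherwise boundaries drift by seconds over
a session.

Gravity removal (needed only for the acceleration-magnitude analysis)
subtracts the per-channel median over quiescent windows (1 s windows whose
pooled acceleration SD is below 0.15 m/s²); without any quiescent window it
falls back to subtracting 9.81 from the vertical axis. Classifier features
deliberately operate on gravity-inclusive signals: the pitch feature *is*
the orientation of the gravity vector.

## Features

Eight classical window features, with the standard definitions frozen here:
`rms = sqrt(mean(x²))`, `mean`, `signal_energy = sum(x²)/n`, lag-1 Pearson
autocorrelation (lag configurable), pairwise Pearson correlation within a
sensor (zero-variance axes yield 0 so static windows stay finite),
`sma = (Σ|x_v|+Σ|x_ml|+Σ|x_ap|)/n` per sensor, sample SD, and pitch — the
window mean of `atan2(acc_ap, hypot(acc_v, acc_ml))` in degrees, positive
for a forward lean. Each feature is computed over a configured scope
(accelerometer, gyroscope, or both); extraction is vectorized over windows
and bit-reproducible.

## Hierarchical classifier

Three stages, each with its own window geometry, filter and feature set
(defaults in `chairrise.classify.default_configs`):

| stage | model | window / step | filter | role |
|---|---|---|---|---|
| state | gradient-boosted trees (100 × depth 3) | 1.405 / 0.072 s | 6.1 Hz | static / dynamic / transition |
| static | MLP, 5 hidden layers × 7 nodes | 2.511 / 0.427 s | — | SIT vs STAND |
| transition | MLP, 4 hidden layers × 40 nodes | 1.135 / 0.073 s | 4.5 Hz | SIT_STAND vs STAND_SIT |

Model internals not fixed by the architecture (optimizer, iteration caps,
feature standardization for the MLPs) are documented defaults with a fixed
seed; no result in this package depends on exact learned weights. Window
ground truth is assigned by majority time-overlap with the label track,
ties broken toward the transition classes (transitions are short and rare;
recall matters most). Stage 2 trains only on windows whose majority label is
a posture, stage 3 only on transition-majority windows. At prediction time
the stage-2/3 decisions are merged onto the state grid by nearest window
center; `dynamic` windows terminate at the DYNAMIC label (no third stage-2
classifier — the vocabulary has no finer dynamic classes).

Window labels become a segment track via a mode filter (default width 3
windows), run merging with boundaries at midpoints between window centers,
and finally absorption of segments shorter than 0.5 s into their longer
neighbour. The last step goes beyond plain mode filtering: isolated
sub-second label runs are almost always classifier noise at this grid step
(0.07 s), and they are what breaks the sequence grammar. True activities
survive: transitions last ≥ 0.8 s, and a static hold that is genuinely
shorter than 0.5 s is legitimately absorbed because the grammar allows a
rise to follow a descent directly. Cross-validation groups folds by subject
to prevent leakage — grouping is the package's choice.

### Duration calibration

Majority-overlap labelling places the boundary between a rise and the next
descent at the midpoint of the (often invisible) static hold between them,
so a detected test ends roughly half a hold late; window quantization adds
jitter. This is the window-level analogue of the systematic offset any
IMU-based timing shows against a stopwatch, and it is handled the same way:
a linear regression of detected against reference durations
(`ActivityClassifierResults.calibrate_duration`, fitted on labelled
training sessions only) whose inverse
(`bias_correct_duration(t, slope, intercept)`) maps detected durations onto
the reference scale. The shipped default coefficients (slope 0.902,
intercept 1.96) are the published stopwatch-vs-IMU fit for this test family
and should be replaced by a local calibration when one is available.

## Valid-sequence grammar

A valid 5CRT is five rises, each followed — directly or via a static hold
bounded by `max_hold_s` (default 30 s, to keep two separate tests from
merging) — by a descent; SIT holds may separate cycles. The two natural
readings of the rule set conflict: five full cycles require five descents,
but the test clock stops at the end of the fifth rise, after which the
subject's final sit-down is not part of the timed test. Resolution: a
detected test requires **5 rises and at least 4 descents**; the fifth
descent is attached when it directly follows, and all averaged descent
statistics use exactly the first four. Any DYNAMIC/OTHER segment, over-long
hold, or gap (> 0.01 s) inside a candidate aborts it. Matching is greedy
left-to-right, so back-to-back tests are detected separately and never
overlap. Total duration is first-rise onset to fifth-rise end; an option
includes the final descent.

Scoring bands (0–4 points) have 0.01 s gaps as printed (… ≤ 11.19,
11.20–13.69 …); durations are rounded to 2 decimals before lookup so the
function is total and monotone non-increasing with exactly five plateaus.

## Force-plate phase analysis

Per rise: seat-off is the upward crossing of
`resting_weight + 0.5·(body_weight − resting_weight)`; the peak is the
maximum after seat-off (overshoot = peak − body weight); full stand is the
first re-entry into `body_weight ± 2%` after the post-peak dip that persists
for ≥ 0.25 s. The 50% threshold, ±2% band and 0.25 s dwell have no standard
values; they are package defaults, configurable per call.
Body and resting weight are taken from metadata when present, otherwise
estimated as the median vertical force over the detected test's STAND and
SIT segments. Cycles without a threshold crossing or a sustained band
re-entry are returned flagged unsegmentable rather than dropped.

## Agreement and similarity analytics

`agreement(x, y)` is ordinary least squares of y on x with Pearson r and a
two-sided p-value, plus Bland–Altman statistics of the differences `y − x`
(sample SD; limits of agreement mean ± 1.96·SD). The significance threshold
is configurable: 0.05 by default, since both 0.05 and 0.005 are defensible
and published practice for these analyses is inconsistent.

`normalized_xcorr` computes, at each lag within
`|lag| ≤ max_lag_fraction · min(len)`, the Pearson correlation of the
overlapping parts, and returns the maximum — invariant to positive affine
amplitude transforms, exactly 1 for a pure shift within the lag bound.
Cycle waveforms are compared on the vertical force by default;
`time_normalize` (linear resampling onto a fixed abscissa count) removes
duration differences first, which is the right mode for inter-person
comparison of movement *forms* and the default for the similarity matrix.
Whether raw-lag or time-normalized comparison is the "correct" published
procedure is ambiguous; both modes are provided. Correlation magnitudes are
labelled by the usual rule of thumb (≥ 0.9 very high, 0.7–0.9 high,
0.5–0.7 moderate, 0.3–0.5 low, else negligible).

## Synthetic test bed

The generator emulates the canonical chair-rise signal morphology from a
single latent phase timeline, so IMU and force are cross-consistent by
construction. Waveforms are piecewise raised-cosine segments between
control points — smooth, parameter-interpretable, and analytically
invertible, so the generator can report *exact* ground-truth seat-off, peak
and full-stand times for every programmed rise.

A subject is a scalar `fitness ∈ [0, 1]`: per-rise duration maps linearly
to 2.0 → 0.8 s, force overshoot to 0.05 → 0.35 of body weight, and
mediolateral sway scales with `1 − fitness` — so fit subjects show a larger
dynamic force range and less sway, the contrast reported between fast and
slow performers. Descents take 1.1× the rise duration; cycles slow down by
2% per cycle (late-test fatigue) with 3% duration jitter. The resting
weight while seated defaults to 0.35 of body weight (unquantified in the
source; configurable). Sessions embed the test in non-test activity —
standing (as in the balance assessments that accompany the test in
practice), a band-limited oscillatory walking surrogate, and a seated
preparation block of several seconds (the subject sits and waits for the
start signal; this also guarantees the 2.5 s static-stage windows see pure
sitting). Sensor noise is white Gaussian (default SD 0.15 m/s² on
acceleration, 5× that in deg/s on gyro, 10× in newtons on force); the real
sensor's noise spectrum is unpublished, so white noise is the stand-in.

Cohorts draw target total durations latin-hypercube style over 9.2–16.8 s,
matching the reference population's range (9.08–16.27 s, mean 12.04 s), and
derive fitness and hold lengths from each target; for cohorts of ≥ ~8
subjects the induced distribution spans the 4-, 3- and 2-point scoring
bands by construction. `corrupt_session` produces negative controls whose
truth track violates the grammar (a dropped rise, an injected DYNAMIC
block, truncation after the third rise).

**What passing tests show, and what they do not.** The synthetic bed proves
the pipeline's mechanics: correct grammar, exact truth-track timing,
phase-landmark recovery to ±0.05 s on noise-free traces, classifier
separability and end-to-end duration recovery under the generator's noise
model. It does not certify performance on real recordings: real transitions
vary in waveform far beyond a raised-cosine family, sensor placement drifts,
non-test activities are richer than the surrogate, and real label
boundaries are themselves uncertain. Published transition-recognition scores from hip-worn-sensor studies
(F1 around 0.95) are not reproducible here because no such dataset ships
with the package; the cross-validated F1 on synthetic cohorts measures the
pipeline, not any recorded cohort.

## Numerical and degenerate-input choices

* Zero-variance axes in any correlation yield 0 with a log note, not an
  exception; `normalized_xcorr` on a constant series is an error
  (self-similarity of "nothing" is undefined).
* `evaluate` returns 0 for zero-denominator precision/recall/F1.
* Fastest/slowest cycle ties break to the earliest index.
* Scoring accepts an `"incomplete"` sentinel (or None/∞) → 0 points;
  non-positive durations are errors.
* The alignment lag search is bounded (±2 s) and the correction threshold
  (0.05 s) keeps the operation idempotent.
* Model archives are versioned pickles carrying the config fingerprint;
  loading an unknown version fails loudly.

## Problem sizes used in the shipped checks

Detector controls run on 50 valid and 50 corrupted seeded tracks; the
end-to-end duration and F1 checks use one 20-subject cohort under
subject-grouped 5-fold cross-validation with fold-internal duration
calibration; similarity orderings use 6–8-subject cohorts. These sizes were
chosen as the smallest at which the cohort-level claims (band coverage,
intra- vs inter-subject ordering, 90th-percentile recovery) are meaningful.

## Known limitations

* SIT and STAND are distinguished mainly by pitch; a sensor mounted
  without a consistent pelvic tilt contrast would defeat the static stage.
* Static holds shorter than half a state window are invisible at the window
  level; their duration is split between the surrounding transitions (the
  calibration absorbs the systematic part of this).
* The detector consumes maximal matches greedily; a malformed first
  candidate can shadow an overlapping later valid start within the same
  segments (not observed in practice; tracks are short).
* Dynamic time warping, sub-phase similarity and power estimation from
  duration are out of scope.
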