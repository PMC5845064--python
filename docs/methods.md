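# Methods

`lapskill` rates performances of a laparoscopic intracorporeal suturing
task from instrument motion alone. This note records the models, the
numerical choices, and the limits of what the synthetic experiments can
show.

## Problem and data model

A trial is one attempt at suturing inside a pediatric box trainer,
recorded by three 6-DOF magnetic tracking sensors (one on each tool
shaft, one on the endoscope) at approximately 20 Hz, plus two
flex-sensor voltages from the tool handles. Ground truth is an expert
OSATS rating: five domains scored 1–5, summarised as a summed score
(5–25) and a rounded average (round(summed/5)). The pipeline maps a
trial to 280 motion-analysis features (MAFs) and regresses the rating on
them.

On disk a trial is a single CSV (`t, channel, x, y, z, qw, qx, qy, qz,
voltage`) with a JSON metadata sidecar. Units are cm, degrees, seconds,
volts everywhere; orientations are stored only as unit quaternions
(w, x, y, z) — Euler angles are always derived.

## Calibration

**Tip (pivot) calibration.** The tracking sensor sits on the shaft
2–3 cm from the tip. With the tip held stationary at unknown world point
`c`, each sample satisfies `p_i + R_i·o = c`; stacking over samples
gives a linear system in `(o, c)` solved by least squares. This is
algebraically the same geometry as fitting a sphere of radius `|o|` to
the sensor positions, but the linear form also yields the sensor-frame
offset direction and is closed-form and unconditionally stable. A
degenerate recording (insufficient rotation diversity) is detected by
the smallest singular value of the stacked system (threshold 1e-3) and
rejected rather than fitted.

**Grip calibration.** Each handle posture (open / closed; the needle
driver adds a closed-unratcheted anchor) is held for ~5 s; the first and
last 0.5 s of each segment are trimmed as repositioning transients and
the remainder averaged. The voltage→angle map is piecewise linear
through the anchors and clips to the terminal angles outside the
calibrated range (with a warning, never a failure). The handle angles
themselves are configuration, defaulting to 30° open, 0° closed, 3° at
the needle driver's unratcheted stop; no authoritative values exist, so
they are documented and overridable.

**Field-of-view cone.** The endoscope view is a cone (apex, axis,
half-angle) in the scope-sensor frame, fitted to boundary points traced
at two or more distances from the lens. Initialisation is geometric: fit
a circle to each traced cluster (plane SVD + Kåsa fit), extrapolate the
apex along the line through the circle centres by similar triangles,
and set the half-angle to `atan(Δr/Δd)`. Refinement minimises the
angular residuals (angle of each point about the axis minus the
half-angle) with bounded Levenberg–Marquardt iterations; the refined
solution is only accepted if its residual sum does not exceed the
initialiser's. The traced points are assumed to lie **on** the cone
boundary; if the traced circle merely filled the view the recovered
half-angle would be biased low, which a user can correct by tracing a
boundary circle.

## Kinematics

Processing order is fixed: **filter → resample → transform →
differentiate**, each channel filtered at its native (median) rate
before interpolation.

**Low-pass filter.** Fourth-order Butterworth, 6 Hz cutoff, applied
zero-phase. Because the cutoff lies at 0.6 of the Nyquist frequency
(10 Hz at the 20 Hz acquisition rate), a bilinear-transform recursion
warps the response severely in the upper band (a two-pass recursive
filter attenuates an 8 Hz tone by ~700×, where the Butterworth
characteristic specifies ~11×). The filter is therefore realised in the
frequency domain with exactly the two-pass (squared) Butterworth
magnitude `|H(f)|² = 1/(1+(f/fc)^8)` and identically zero phase, after
odd-reflection edge padding of `3·(order+1)` samples. DC gain is exactly
1; inputs shorter than the padding are rejected.

**Resampling.** All channels are interpolated onto an exact 0.05 s grid
spanning the common recorded range (no extrapolation; the grid is
truncated instead). Scalars and positions interpolate linearly;
quaternions are sign-aligned to one hemisphere, slerped on the rotation
manifold, and renormalised.

**Transform.** Tip position is `p + R·o` with the calibrated offset.
Orientation is expressed as intrinsic Z–Y–X Euler angles — azimuth,
elevation, roll, the magnetic tracker's vocabulary — unwrapped over time
so angular path lengths and rates are well defined. Proximity to gimbal
lock (|elevation| > 85°) is logged. Grip voltage passes through the same
filter/resample pipeline before the calibration map converts it to an
angle.

**Derivatives.** Central differences in the interior, one-sided at the
ends (exact for quadratics in the interior). Angular rates are
component-wise derivatives of the unwrapped Euler angles.

**Visibility.** Each tip is transformed into the scope-sensor frame and
tested against the cone: in the forward half-space of the apex and
within the half-angle of the axis. There is no far limit, and a tip
coincident with the apex counts as not visible. Occlusion by tissue or
the other instrument is out of scope — this is a purely geometric test.

## The 280 features

Four categories: time (5), tip visibility (8), grip (20), tip motion
(247). The tip-motion itemisation (per-tool per-axis path lengths,
bounding-box diagonal, average and instantaneous velocity/acceleration
statistics, needle/maryland ratios, cross-tool sums, and peak rates at
fixed thresholds) is normative for this package and version-locked in
`features.maf_manifest()`; models and persisted files reference features
by manifest name.

Numerical conventions that matter:

* a *peak* of a magnitude series is a sample strictly above its
  predecessor, at or above its successor, and at or above the threshold;
  peak counts are divided by trial duration;
* "stationary" on a noisy grip signal means |velocity| ≤ 1 °/s
  (acceleration: ≤ 10 °/s²); both thresholds are configurable module
  constants;
* needle/maryland ratios with denominator magnitude < 1e-9 map to 0 (a
  standardised design matrix cannot carry infinities); the time-in-view
  and time-out-of-view of each tool always sum to the trial duration.

Per-axis features are tied to the world frame by definition (an X path
length changes if the world frame rotates); only the magnitude-based
features are rotation invariant, and the tests distinguish the two.

## Modelling and evaluation

Features are standardised with training-set mean/sd (zero-variance
columns dropped and recorded). An elastic net fitted to the summed score
selects features: the l1 mixing ratio is searched over
{0.5, 0.7, 0.9, 0.95, 1.0} jointly with the penalty strength by inner
5-fold CV on mean squared error (20 penalty values along the
regularisation path — coarser than scikit-learn's default 100, which
changes the selected set negligibly at n ≈ 60 while keeping a full
leave-one-subject-out run under half a minute). An all-zero fit falls
back to a constant training-median model.

The default predictor fits one regression tree per OSATS domain on the
selected features (minimum leaf 3, cost-complexity pruning chosen by
inner CV over ≤ 8 quantiles of the pruning path) and sums the five
outputs; a single summed-score tree is available as a configuration.
Summed predictions are rounded and clipped to [5, 25]; the rounded
average is round(summed/5).

Evaluation is leave-one-subject-out: one fold per subject (sorted
order), with standardisation, selection, and fitting recomputed inside
each fold — no statistic of a held-out subject touches training, which a
label-perturbation test asserts directly. Metrics: summed-score accuracy
within ±2 and ±4 points, rounded-average accuracy exact and within ±1,
and Pearson r for both scales (reported as NaN against a constant
prediction, as for the median baseline). The confusion matrix is 5×5
even when no score of 5 occurs. Controls: a uniform random guesser on
summed scores 5–20, and the constant training median. All stochastic
steps (inner-CV shuffling, tree tie-breaking, the random baseline) take
explicit seeds.

Open modelling choice: selection is driven by the summed score only
(the per-domain trees then share one selected set) rather than
re-selecting per domain; summed-score selection is the only procedure
with an authoritative description, and it keeps the five trees
comparable.

## Synthetic cohorts

The generator emulates the study conditions — 32 subjects (6 medical
students, 21 residents, 5 fellows), two trials each, ~20 Hz jittered
sampling, sensor quantisation of 0.14 cm and 0.5°, trials capped at
600 s — with latent skill `s ∈ [1, 5]` driving every observable
monotonically:

* duration `T(s) = 480·e^{−0.45(s−1)}` s (≈ 480 s at s = 1, ≈ 124 s at
  s = 4), lognormal trial-to-trial jitter, hard cap at the acquisition
  limit;
* tool tips follow minimum-jerk sub-movements between via-points near
  the simulated tissue (the motor-control standard for smooth reaching);
  lower skill means more corrective sub-movements per second and larger
  Gaussian tremor (amplitude 0.05·(5−s) cm), which is exactly what the
  path-length and peak-rate features measure;
* the needle driver drifts out of the camera cone in discrete episodes
  (rate ∝ (5−s)); ordinary working via-points are kept inside the view,
  so the out-of-view fraction isolates this skill signal;
* grip events (close–hold–open through the inverse calibration map) come
  at a rate and abruptness that grow as skill drops;
* per-subject skill is drawn by training level (students ≈ 1.35 ± 0.35,
  residents ≈ 2.9 ± 0.55, fellows ≈ 3.6 ± 0.3) and a non-negative
  learning gain (≈ 0.25) applies to the second trial, reproducing the
  strong first-trial/second-trial score correlation.

Skill expresses itself through three partially independent channels: the
trial's motion, grip, and visibility behaviour each follow a perturbed
per-trial skill `s_c = s + η_c`, `η_c ~ N(0, 0.5)`, and the simulated
rater scores the realised performance (the mean of the three). This is
the realistic structure in which sensor fusion pays: a model seeing only
time and tip motion can estimate the motion channel well but not the
grip and visibility channels, so the all-sensor model carries strictly
more information about the rating. The rater adds correlated noise per
domain (`σ = 0.4`, half the variance shared across domains) and clips to
the 1–5 scale.

What the generator does **not** emulate: contact dynamics of needle and
tissue, occlusion, magnetic-field distortion, sensor dropout, or any
biomechanically realistic suturing strategy. Passing end-to-end tests
therefore demonstrates that the pipeline recovers a skill signal with
the assumed statistical structure at realistic noise levels — not that
it reproduces the accuracies reported for the original recordings, which
were never deposited.

## Problem sizes used in the packaged experiments

The end-to-end experiment simulates five independent default cohorts
(5 × 64 trials), runs the full pipeline on each, and averages
leave-one-subject-out metrics for the TMVG and TM sensor subsets.
Calibration recovery uses 200-pose pivot recordings and 80-point cone
traces (50 Monte-Carlo repetitions at sensor resolution); the visibility
oracle uses 10⁴ random points; filter checks use 60 s tones. These sizes
give seed-stable averages while keeping a full run of the experiment
suite in the minutes range on one core.

## Known limitations

* The tip-motion itemisation cannot be uniquely recovered from its
  source description; the manifest here is one consistent reconstruction
  locked to the printed category totals (5/8/20/247 and per-subset
  5/25/252/260/272/280).
* Euler-rate "angular velocity" is the tracker convention, not the body
  angular-velocity vector; near gimbal lock the elevation rate is
  ill-conditioned (logged, not corrected).
* The frequency-domain filter realisation is periodic in nature;
  odd-reflection padding suppresses wrap-around at the cost of treating
  the signal ends as locally odd-symmetric, the same convention as
  `filtfilt`'s default padding.
* Whether orientation and voltage channels were filtered in the original
  system is unknown; this package filters all channels uniformly.
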