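# Methods

`kinagree` models the concurrent validation of a single body-worn IMU
rehabilitation device against optoelectronic motion capture (MoCap), the
gold standard for human-movement kinematics. This note documents the
models, the statistics, the numerical choices, and what the synthetic data
do and do not establish.

## The measurement setting

A subject wears one IMU on the trunk or thigh and performs guided motor
tasks (semi-squat, hip abduction/flexion/extension, knee extension,
anterior trunk flexion, lateral trunk bending), 10 repetitions per task
(10 per side for bilateral tasks), while both systems record
simultaneously. The device reports absolute segment orientation as unit
quaternions at 30 Hz; its Euler decomposition is intrinsic ZYX with the
first (Z) angle the flexion/extension component, the middle (Y) angle
internal/external rotation (the segment's longitudinal axis) and the last
(X) adduction/abduction. The MoCap pipeline delivers absolute segment
angles at 100 Hz from an intrinsic YXZ decomposition of marker-derived
rotation matrices. Both sequences are treated as intrinsic; the device
family's firmware and standard gait software use intrinsic conventions,
and the round-trip and composition tests pin the implementation to
closed-form matrix formulas rather than to any one library's convention.

The outcome per repetition is the range of motion (ROM): how far, in
degrees, the segment was excursed and *held*.

## Synthetic sessions

Real paired recordings for this protocol are not publicly deposited, so
the package generates them. One session is:

- a lead-in rest (3 s) containing the synchronization artifact — the
  subject stamps a foot at t = 1 s, producing three Gaussian spikes
  (sigma 40 ms, 120 ms apart, amplitude 20 units) in the IMU's x-axis
  acceleration and in the reference marker trajectory;
- `n_repetitions` cycles of rest–ramp–hold–return about a single motion
  axis: smoothstep (C1) ramps of 0.3 s, a plateau of 10 s at the task's
  target ROM, 1.7 s of rest. The plateau dominates the cycle because the
  device's biofeedback instructs the subject to reach and hold the
  target; a long hold also makes the working-phase mean (below) a clean
  estimator of the plateau value. Per-task target ROMs default to the
  reference cohort's MoCap means (`kinagree.reference`).

Corruptions, each with a known injected value: white Gaussian angle noise
(0.5° MoCap, 1.0° IMU — the device datasheet states only a <5 % error
bound, so these are plausible mid-range values); a constant inter-system
offset added to the MoCap trace (default 2°); an integer-sample clock lag
of the IMU stream (default 0.5 s = 15 samples); sensor misplacement
(below); and an optional device-side ROM bias that scales the IMU
rendering so its plateau sits at `target + bias`, the knob cohort
simulations use to emulate a systematic between-system discrepancy.

What the generator does **not** model: soft-tissue artifact, orientation
drift, Kalman-filter dynamics, cross-plane physiological coupling,
marker occlusions, or fatigue trends. Passing tests therefore demonstrate
that the *pipeline* recovers what it claims from signals with realistic
rates, noise and artifacts — not that the physical device meets any
accuracy figure on real subjects.

## Misplacement model

The displacement protocol moves the thigh sensor 10 % of the thigh
diameter around the circumference, medially or laterally. Arc length over
radius converts this to a fixed axial rotation theta = (0.1 d)/(d/2) =
0.2 rad ≈ 11.5° of the sensor frame about the segment's longitudinal (Y)
axis. The remounted sensor sees the segment rotation conjugated into its
own frame, `q' = r⁻¹ q r`. Note that pre-multiplying alone (`r q`) would
merely add a constant first Euler angle and leave the extracted
flexion/extension untouched — it is the conjugation that tilts the motion
axis as seen by the sensor and attenuates the in-plane angle to
approximately `A·cos(theta)` (exactly:
`atan2(sin A cos theta, cos A cos²theta + sin²theta)`), symmetrically in
±theta and monotonically in |theta| on [0°, 60°].

Real cohorts show *asymmetric* medial/lateral effects, driven by
compensatory strategies in more than one anatomical plane; a pure
single-plane axial-rotation model cannot reproduce that asymmetry, and the
package does not pretend to — the sensitivity report quantifies the
geometric part only.

## Synchronization

1. The 100 Hz reference trace is anti-alias filtered with a linear-phase
   FIR (cutoff 12 Hz = 80 % of the new Nyquist, ~2 s of taps, zero group
   delay) and polyphase-resampled by 3/10 to 30 Hz.
2. Both artifact channels are passed through the *same* causal third-order
   Butterworth low-pass at 5 Hz. Filtering only one channel (the device's
   acceleration) would shift the correlation peak by the filter's group
   delay; identical filtering cancels it, which is why noise-free
   integer-sample lags are recovered exactly.
3. The spike window is isolated on the reference channel (peaks above 6
   robust SDs, clustered within 0.5 s, padded 0.3 s) and both channels are
   cropped to it plus the ±2 s search range.
4. The integer lag maximizing the normalized cross-correlation (Pearson
   correlation over the overlap, ties broken toward the smallest |lag|) is
   taken. Lag is integer at 30 Hz (~33 ms resolution); no sub-sample
   refinement is attempted because all downstream statistics are
   per-repetition aggregates.
5. The inter-system offset is the difference of rest-phase means (first
   2 s of the aligned traces, inside the lead-in) and is subtracted from
   the IMU trace. Sign convention: offset = IMU rest mean − MoCap rest
   mean. The ROM statistic subtracts a rest baseline anyway, so ROM is
   insensitive to any residual constant offset.

## Repetition segmentation and the ROM statistic

Repetition peaks are detected on a lightly smoothed copy of the trace
(0.3 s moving average, detection only) with prominence ≥ 25 % of the
global excursion; peaks not separated by a valley at least that deep are
merged — a numerically flat plateau can carry several tied micro-peaks,
and without the merge a noise ripple at a plateau edge can masquerade as a
cycle boundary. Boundaries are the minima between consecutive repetition
peaks plus the minima before the first and after the last. A count that
disagrees with the expected repetition number warns with diagnostics and
never silently truncates.

Each cycle is resampled to 101 points by linear interpolation (the
gait-cycle convention) and amplitude-normalized to [0, 1]. The *working
phase* is the longest contiguous run with normalized value ≥ tau = 0.9.
The window is located on a 5-sample smoothed copy of the cycle: if the
raw samples were thresholded, the noisy maximum would inflate the
threshold and only positive-noise samples would survive it, biasing the
working-phase mean upward by several tenths of a degree at 1° sensor
noise; selecting on the smoothed cycle and averaging the raw samples
removes that selection bias (verified against injected ground truth).

ROM = mean raw angle over the working phase − rest baseline (mean of the
pre-task rest window). The plateau mean, rather than max-minus-min,
measures how well the subject *maintains* the excursion and is immune to
single-sample overshoots; max-minus-min and a "final position" variant
(last working-phase sample minus baseline) are exposed as secondary
diagnostics only. Because smoothstep ramps spend time between 0.9·A and A,
the working-phase mean sits slightly below the plateau; with the default
0.3 s ramps and 10 s holds that deficit is below 0.02° for every task
template, which is what lets noise-free end-to-end recovery meet a 0.1°
tolerance.

Bilateral tasks are pooled (20 repetitions, 10 per side) only when a
paired t-test on matched per-repetition ROMs finds no significant side
difference (p > 0.05); the pre-test's own 5 % false-positive rate means a
simulated participant occasionally keeps a single side, by design. The
test choice is ours — the protocol's source does not name one.

## Agreement statistics

Computed on per-participant mean ROM pairs (n = participants, default 21),
not per-repetition values:

- **Accuracy** = (1 − |ROM_IMU − ROM_MoCap| / ROM_MoCap) × 100, on the
  cohort means.
- **RMSE** = sqrt(Σ(ŷᵢ − yᵢ)²/n) over paired per-participant means.
- **Pearson r** with two-sided p (t transform).
- **Lin's CCC** = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with 1/n moments, the
  original concordance estimator's convention (noted because n is small);
  |CCC| ≤ |PCC| holds identically and is property-tested.
- **Bland–Altman**: bias = mean difference, LoA = bias ± 1.96 sd(diff),
  with the (mean, difference) pairs exported for plotting.
- **SEM / MCID**: SEM = SD·sqrt(1 − R), MCID = 1 SEM, flagged when the
  mean |difference| exceeds it. The reliability ratio R (MoCap variance
  over IMU variance) can exceed 1 on data, making sqrt(1 − R) undefined
  under a literal reading; this implementation clamps R to
  min(ratio, 1/ratio) and uses the pooled SD
  sqrt((SD_IMU² + SD_MoCap²)/2), keeping the SEM real and symmetric in the
  two systems. This is a declared convention of the package: published
  MCID values for this protocol are not reproducible from their printed
  SDs under any literal reading of the formula.
- **Anderson–Darling** normality check with the D'Agostino–Stephens
  small-sample correction and p-value approximation (both parameters
  estimated) — implemented in-package because scipy exposes only the
  statistic and critical values. Monte-Carlo tests pin its type-I rate to
  3–7 % at alpha = 0.05 and its power against uniform data.

No multiple-testing correction is applied across tasks, matching the
protocol being modeled.

## Cohort studies

`run_validation_study` simulates per-participant sessions (task targets
spread with SD 5° between subjects, per-participant device bias spread
with SD 2° around the configured task bias), runs the full pipeline per
session, pools sides, builds per-task agreement reports, and runs the
correct/medial/lateral misplacement arms for the two hip tasks. Session
seeds derive from the master seed through `SeedSequence(entropy, spawn_key)`
per (task, participant, side), so any single session is reproducible in
isolation. A full 7-task, 21-participant study takes on the order of ten
seconds; all emitted summary numbers are recomputable from the emitted
per-repetition ROM table (tested).

## Degenerate inputs and numerical conventions

Angles are degrees at every API surface. Quaternions are scalar-first and
validated to unit norm (1e-6); q and −q are one orientation. Middle Euler
angles within 0.01° of ±90° raise a gimbal-lock warning; the in-scope
tasks stay far from the singularity. Constant traces fail segmentation
explicitly; flat cycles have no working phase; a zero reference ROM makes
accuracy undefined (raised, not NaN). Cross-correlation of constant
windows is rejected. CSV exports use fixed 6-decimal formatting so equal
seeds give byte-identical files.

## Known limitations

- The symmetric axial-rotation misplacement model cannot reproduce
  asymmetric medial/lateral shifts seen in vivo (an optional cross-plane
  coupling would be needed; the default model is deliberately minimal).
- Lag is constant per session; clock drift is out of scope.
- The working-phase statistic assumes hold-type tasks; for ballistic
  movements with no plateau the tau = 0.9 window degenerates toward the
  peak and the statistic approaches a peak mean.
- Synthetic noise is white; real sensor error is autocorrelated and
  drift-prone, so real-data performance bounds cannot be inferred from
  these simulations.
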