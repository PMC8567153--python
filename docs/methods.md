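# Methods

## Problem and model

`imuwrist` measures the wrist joint angle with two 9-axis inertial
sensors — one on the back of the hand, one on the forearm just above the
wrist — mounted so their Y and Z axes are parallel and the X axes point
toward the wrist centre. With this geometry the joint movement is a
single rotation about the shared Y axis, and the joint angle is simply
the difference between the two sensors' orientations on the X-Z plane.
No global reference frame, Euler angles or quaternions are needed: only
relative motion enters the measurement, so slow environmental effects
cancel between the sensors.

Each sensor's X-Z orientation is tracked by a first-order complementary
filter that blends two observations of the same angle:

- **Accelerometer tilt.** When the sensor is quasi-static the
  accelerometer reads gravity, and the tilt on the X-Z plane is the
  four-quadrant arctangent `beta = atan2(a_x, a_z)` (degrees, in
  (−180, 180]). This observation is drift-free but noisy and corrupted
  during fast movement.
- **Gyroscope integration.** The Y-axis angular rate integrates to a
  smooth angle but accumulates error from the gyro's bias and noise.
  The rate is therefore corrected before integration (next section).

The filter update is

    sigma[k] = h * (sigma[k−1] + omega_gf[k] * dt) + l * beta[k],

with the high-pass weight `h` and low-pass weight `l` constrained to
`h + l = 1` (enforced at construction; violating configurations cannot
be built). The recurrence is evaluated with a vectorized first-order IIR
filter, which is bit-identical to the per-sample loop. The filter state
is initialized from the first accelerometer tilt sample of the
(trimmed) stream. Defaults `h = 0.98`, `l = 0.02` at 100 Hz give the
gyro path a time constant of about 0.5 s — long enough to reject tilt
noise, short enough that the accelerometer pins the low-frequency angle
within any realistic hold phase.

Only the X-Z angle is fused into the joint measurement (the two-sensor
geometry reduces the problem to 2-D). The companion projections
`theta_yz` and `theta_zy` are computed and exposed for inspection but do
not enter the joint angle.

## Gyroscope drift correction

Two corrections are applied to the raw angular rate:

1. **Average static drift.** The constant bias is the mean reading over
   `m` stationary windows of `window_len = 100` samples, window `j`
   starting at sample `n + j·r` (defaults `n = 0`, `m = 5`, `r = 100`,
   i.e. the first five seconds of the stationary lead-in at 100 Hz).
   The series must be strictly longer than `n + (m−1)·r + 100·m`
   samples; shorter series raise a sample-count error citing the bound.
2. **Savitzky–Golay calibration.** After bias removal the rate is
   smoothed with a zero-phase Savitzky–Golay polynomial filter
   (defaults: window 51 samples ≈ 0.5 s, order 3). The smoother
   suppresses the wideband sensor noise that would otherwise integrate
   into a random walk, while passing the slow, smooth movement signal
   essentially unchanged (a 1 Hz component loses about 2% through the
   default window; wrist-task energy sits well below that).

A design point worth stating explicitly: the Savitzky–Golay filter
*smooths the corrected rate*; it is not subtracted from it. Subtracting
the smoothed residual would high-pass the gyro channel and null the very
movement signal the filter path exists to carry — the accelerometer
would then be the only source of low-frequency angle and peak tracking
would lag by the filter time constant. The smoothing reading keeps the
gyro informative and is the one under which a rate of "true signal +
constant bias" is restored to the true signal. Residual slow drift that
survives both corrections (e.g. the simulator's linear ramp) is bounded
by the complementary filter's accelerometer coupling rather than
accumulating.

## Synthetic motion and sensor model

No public recordings exist for this task, so the package ships a
simulator that defines the study conditions end to end.

**Trajectory.** The stop-sign task is a cosine-blended trapezoidal
ramp–hold–ramp: angular velocity rises to the requested `speed` through
a half-cosine blend (blend time = 0.2 × peak/speed), cruises, and decays
symmetrically, so the peak angular velocity equals `speed` exactly and
the peak angle is reached in closed form. The profile starts and ends at
0°; an optional stationary `lead_in` precedes the movement (cohort
default 6 s, leaving ≥ 5 s of static data after the 1 s startup trim for
the drift windows). An optional tremor sinusoid (amplitude in degrees,
frequency in Hz) is superposed on the whole trajectory.

**Sensors.** The forearm sensor stays level and the hand sensor rotates
by the joint angle about the shared Y axis (a `forearm_fraction`
parameter splits the rotation between the sensors for the both-moving
validation mode). Accelerometers read the gravity unit vector rotated
into the sensor frame plus white noise; gyroscopes read the true rate
plus a per-axis static bias, a common linear drift ramp, and white
noise; magnetometers read a fixed ambient field rotated into the frame
plus noise. Lever-arm (tangential/centripetal) acceleration is *not*
modelled — noise-free accelerometer magnitude is exactly 1 g — so the
simulator does not exercise the accelerometer-corruption failure mode of
fast real movement; the validation envelopes below should be read with
that in mind.

**Noise defaults** (consumer MEMS scale): accelerometer sd 0.01 g; gyro
sd 0.2 °/s, static bias (0.6, −0.4, 0.5) °/s, drift 0.005 °/s²;
magnetic field (22, 5, −42) µT with sd 0.5 µT.

**Cohort contrast.** The impaired class (label 1) defaults to peak angle
40° at 20 °/s with a 2° / 5 Hz tremor; the typical class (label 0) to
70° at 40 °/s, no tremor. Per-trial jitter: 15% relative sd on peak and
speed, 25% on tremor amplitude, 10% on tremor frequency. These effect
sizes are artifact choices encoding "reduced, slower, shakier movement";
they are not estimates of any clinical population, so classifier
accuracies on the synthetic cohort say nothing about clinical accuracy —
they verify the pipeline, not the clinic.

## Features

Each trimmed trial yields 18 channels (2 sensors × 9 axes). Every
channel is mean-detrended and Fourier-transformed over the whole trial
(no window function), so the fundamental frequency is `1/t_total` and
equals the bin spacing. Amplitudes are normalized so a sinusoid of
amplitude *a* at a bin frequency peaks at *a*. The five
largest-amplitude non-DC bins (ties to the lower frequency) are kept as
the trial's harmonics; their amplitude `A`, phase `P` (radians,
(−π, π]) and frequency `F` (Hz) form the 270-vector

    18 channels × 5 harmonics × {A, P, F}.

Ordering is block-major (A: positions 1–90, P: 91–180, F: 181–270),
channel-major within a block (hand ax…mz then forearm ax…mz), harmonics
innermost; `feature_index` / `FEATURE_NAMES` expose the map. Position 91
is the phase of the leading harmonic of the hand accelerometer X
channel. An alternative harmonic definition — bins at k·f0, k = 1…5,
which makes `F` degenerate — is available as `mode="fundamental"`.

## Benchmark

Stratified 10-fold cross-validation (shuffled, seeded) with pooled
out-of-fold predictions. Accuracy is the pooled fraction correct, in
percent. ROC curves are standard threshold sweeps per class
(one-vs-rest) with trapezoidal AUC; the reported AUC is the
class-prevalence-weighted average, which for a binary problem equals the
plain AUC of the positive-class score.

ZeroR (majority class; ties → label 0; constant scores, AUC 0.5) and
OneR (equal-frequency discretization, default 10 bins with ≥ 6 samples
per bin; per-bin majority labels; lowest-training-error feature wins,
ties to the lower index; constant features skipped, all-constant falls
back to majority) are implemented natively. The remaining algorithms are
scikit-learn estimators with defaults mirroring the common benchmarking
platform: Gaussian naive Bayes; logistic regression (standardized);
entropy-criterion decision tree; 100-tree random forest; RBF SVM
(standardized); one-hidden-layer (64) MLP (standardized); 1-nearest
neighbour (standardized). "BayesNet" has no backing implementation in
the supported stack and degrades to naive Bayes with a logged warning.
Summaries append an unweighted Average row over all non-ZeroR rows,
rounded to 2 (accuracy) / 3 (AUC) decimals.

## Validation experiment and problem sizes

`peak_angle_error_experiment` emulates a robotic validation rig: trials
drive the joint to predetermined peaks (30/50/70/90°) at a fixed joint
speed, either with the forearm sensor static or with both sensors
sharing the rotation, and the mean signed detected-minus-true peak error
is reported. The shipped experiments use 20 trials per condition at
100 Hz with the default noise model; trial durations are extended when
necessary so the post-trim stream still satisfies the drift-window
sample bound. Under these conditions the absolute mean error is about
0.1° (one static or both moving at 30 °/s) and about 0.4° at 90 °/s —
inside the −0.95…0.11°, −0.92…2.90° and −2.63…0.54° envelopes published
for the physical rig, though the comparison is indicative only: the
simulator omits the rig's unmodelled accelerations and mounting errors.

## Numerical and degenerate-input choices

- `fs` is explicit per-trial metadata; the filter `dt` is `1/fs`
  (default 0.01 s at the nominal 100 Hz).
- Startup trim default 1.0 s (round(trim·fs) samples from both streams).
- Tilt of a zero (a_x, a_z) vector, empty trials, mismatched stream
  lengths, non-numeric CSV cells, single-class ROC, k > dataset size all
  raise typed errors; nothing is silently coerced.
- Trial CSVs store 6 decimal places; round-trips are lossless at that
  precision.
- Angle boundary: tilt values of exactly −180° are mapped to +180°.

## Known limitations

- No lever-arm acceleration, magnetometer disturbance, cross-axis
  motion, sensor misalignment or mounting slip in the simulator; the
  drift model is bias + linear ramp + white noise only.
- The complementary filter assumes the accelerometer tilt is an
  unbiased low-frequency observation; sustained high acceleration would
  violate this and is not represented.
- Synthetic class contrast is an artifact parameter; benchmark numbers
  on it validate plumbing and separability mechanics, not clinical
  performance.
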