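# imuwrist

Wrist joint-angle estimation from two wearable inertial sensors, and a
movement-classification benchmark on top of it.

Clinically, active wrist range of motion (ROM) in children with movement
disorders such as cerebral palsy is measured with goniometers — hard to
apply to small, moving hands and blind to movement outside the clinic.
`imuwrist` implements the alternative: two 9-axis IMUs (accelerometer,
gyroscope, magnetometer), one on the back of the hand and one on the
forearm, mounted with parallel Y/Z axes so the wrist angle is a single
rotation about the shared Y axis. The package estimates that angle,
summarizes ROM per trial, turns trials into frequency-domain feature
vectors, and benchmarks a classical classifier suite at separating
impaired from typical movement. Because clinical recordings of this kind
are not public, a built-in simulator generates ground-truth stop-sign
trials (rest → maximal extension → rest) with configurable sensor
imperfections and class contrast; every quantitative claim in the test
suite is made against that simulator's known truth.

## Method

Per sensor, the X-Z-plane orientation σ is tracked by a complementary
filter fusing the accelerometer tilt β = atan2(aₓ, a_z) with the
drift-corrected gyro rate ω_gf:

σ(n+1) = h·(σ(n) + ω_gf·Δt) + l·β(n+1),  with h + l = 1 (default h = 0.98).

The gyro rate is corrected by subtracting the average static drift
(mean over m = 5 stationary 100-sample windows, window j starting at
sample n + j·r) and calibrating the remainder with a zero-phase
Savitzky–Golay smoother (window 51, order 3). The wrist angle is
σ_hand − σ_forearm; no Euler angles or quaternions are involved.

Features: each of the 18 channels is FFT-transformed over the whole
trial (fundamental frequency 1/t_total); the amplitude A, phase P and
peak frequency F of the 5 dominant harmonics per channel give
18 × 5 × 3 = 270 features. The benchmark runs ZeroR and OneR (native
implementations) plus naive Bayes, logistic regression, entropy decision
tree, random forest, SVM, MLP and k-NN under stratified 10-fold
cross-validation, reporting pooled accuracy and class-weighted AUC with
ROC curves. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

```python
import imuwrist as iw

# a noiseless-by-default 70-degree stop-sign trial, fused end to end
profile = iw.generate_stop_sign_profile(duration=15, peak_angle=70,
                                        speed=35, lead_in=6.0)
trial = iw.synthesize_recording(profile, seed=0, label=0)
series = iw.joint_angle_from_trial(iw.trim_startup(trial, 1.0))
print(f"max_angle={series.max_angle:.2f} range={series.range:.2f}")

# validation-rig emulation: mean peak-detection error, both sensors moving
err = iw.peak_angle_error_experiment([30], [30, 50, 70, 90],
                                     "both-moving", n_trials=20, seed=1)
print(f"mean_peak_error={err:.3f}")

# default synthetic cohort, 100 impaired / 100 typical
trials = iw.generate_cohort(iw.CohortSpec(n_cp=100, n_typical=100, seed=0))
data = iw.build_dataset([iw.trim_startup(t, 1.0) for t in trials])
table = iw.run_cv(data, ["ZeroR", "OneR", "NaiveBayes", "RandomForest", "KNN"],
                  iw.CVConfig(k=10, seed=0))
print(iw.summarize(table).to_string(index=False))
```

prints

```
max_angle=70.05 range=70.50
mean_peak_error=0.111
  classifier  accuracy   auc
       ZeroR      50.0 0.500
        OneR      99.5 0.995
  NaiveBayes      99.5 0.995
RandomForest      99.5 1.000
         KNN      99.5 0.995
     Average      99.5 0.996
```

The fused peak (70.05°) recovers the simulated 70° truth to within the
sensor noise; the 0.111° mean peak error at 30 °/s sits inside the
published validation envelope for this class of two-sensor rig; ZeroR's
50.0% is the majority fraction of the balanced cohort, and the large
margins of the other classifiers reflect the deliberately separable
default contrast (reduced peak angle, slower rate, tremor), not clinical
difficulty.

A command-line interface wraps the same pipeline:

```sh
imuwrist run-all --seed 1 --outdir runs/demo    # simulate → fuse → featurize → bench
imuwrist simulate --outdir runs/sim             # trial CSVs + dataset manifest
imuwrist angle runs/sim/dataset.yaml            # per-trial ROM report
```

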