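# Methods

This note documents the models, parameter choices and numerical decisions
behind `zupt_sprint`, and what the synthetic validation does and does not
establish about real sprint data.

## Sensor model

Each channel is described by a `SensorSpec` holding datasheet quantities in
SI units: sample rate, full-scale range, ADC bit resolution, white-noise
density (signal units per √Hz), anti-alias cutoff, and noise-equivalent
bandwidth.  The defaults model a dual-range sprint-grade IMU (Blue Trident
IMeasureU class):

| channel | rate | range | bits | LSB | noise density | cutoff / bandwidth |
|---|---|---|---|---|---|---|
| low-g accel | 1125 Hz | ±16 g | 16 | 0.0048 m/s² | 0.23 mg/√Hz | 473 / 1125 Hz |
| high-g accel | 1600 Hz | ±200 g | 13 | 0.48 m/s² | 0.23 mg/√Hz | 800 / 1600 Hz |
| gyroscope | 1125 Hz | ±2000 °/s | 16 | 0.061 °/s | 0.015 (°/s)/√Hz | 473 / 773.5 Hz |

Gravity is 9.80665 m/s²; g-units and °/s are converted at the I/O boundary
and all internal math is SI.  The per-sample noise standard deviation is
`noise_density·√bandwidth` (≈0.076 m/s² low-g, ≈0.090 m/s² high-g,
≈0.417 °/s gyro); the LSB is `2·range/2^bits`.  Datasheet cutoffs are stored
as printed even where they sit close to Nyquist.

## Synthetic sprint generator

The generator's defaults are the study conditions every recovery test runs
under: ~15 s standing, then 17 strides whose lengths ramp linearly
3.45 → 4.73 m and stride speeds 6 → 9.5 m/s (total ≈69.5 m, the far course
mark), with 150 ms ground contacts.  Kinematic form, per swing:

- **Forward (x)**: minimum-jerk interpolant — position, velocity and
  acceleration continuous, zero at both stance ends.
- **Vertical (z)**: a squared-half-sine lift (peak 0.15 m) blended by a
  quintic so the foot arrives at 3.75 mm height moving down at 1.5 m/s, then
  a 5 ms quintic "landing impact" decelerates it to rest.  The impact's
  ≈450 m/s² peak is the initial-contact signature real foot-strike data
  shows; it far exceeds the ≈110–230 m/s² smooth swing extrema.
- **Orientation**: sagittal pitch `θ = A·sin(2π s(t))` with `s` the
  minimum-jerk time warp, so rate and angular acceleration vanish at both
  stance boundaries.  The amplitude `A` is derived from the profile's peak
  pitch rate (default 1800 °/s, just below the gyroscope range — the
  low-saturation case; sweeping this knob to 3000 °/s reproduces heavy
  spike-shod saturation).  A fixed amplitude can be set instead.
- **Stances** are exactly zero velocity; an option adds ≤0.02 m/s
  micro-motion to stress the stillness detector.

Stride durations are `length/speed`; stance-to-stance spacing reproduces
them exactly, and ground truth (stride lengths, cumulative distances at the
footfalls nearest the ~20 m and ~70 m marks) is read directly off the
constructed footfalls.

The corruption chain per channel: 4th-order zero-phase Butterworth at the
anti-alias cutoff (zero-phase so the lag-alignment test is not confounded by
filter delay), cubic-spline decimation from the 9000 Hz internal rate
(an exact multiple of 1125 Hz; 4× above the highest sensor rate), additive
white noise, quantisation, clipping.  The high-g channel can be delayed by an
integer number of 1125 Hz samples — the inter-accelerometer phase offset the
conditioning stage recovers.  Identical seeds give bit-identical recordings.

**What the generator does not emulate**: a true standing-start acceleration
phase (the first stride is already 3.45 m), lateral/frontal-plane motion and
heading drift (y ≡ 0, yaw ≡ 0), soft-tissue and mounting resonances,
temperature-dependent bias, axis misalignment, and non-ideal stance contact
(sliding, compliant midsoles).  Passing recovery tests therefore shows the
*algorithm* is correct under the stated sensor physics, not that any given
shoe/sensor combination achieves these errors in the field.

## Conditioning choices

- Saturation is flagged at 98% of range (any axis) and the mask dilated by
  2 samples per side before fusion, guarding against near-rail distortion.
- Cross-correlation runs on the resultant magnitudes (orientation-
  independent) over the whole trial, normalised per overlap, lags within
  ±56 samples, ties toward the smaller |lag|; the high-g stream is shifted
  by the winning integer lag and zero-padded.  Sub-sample alignment is
  deliberately not attempted.
- The standing window is auto-detected as the first ≥5 s run of 0.25 s
  blocks whose gyro-magnitude deviation stays below 0.05 rad/s, trimmed by
  0.1 s, falling back to [0, 15] s.  Bias estimation refuses windows
  shorter than 2 s or with |gyro| scatter above the threshold ("not still").

## Segmentation choices

- Initial contacts: greedy descending-height peaks of the fused resultant
  acceleration, ≥0.3 s apart, above 3 g (else "no running detected") and
  above 40% of the tallest peak.  The relative floor exists because the
  first swing out of the standing start has no preceding contact within the
  separation window to suppress its swing-acceleration maximum.
- Candidate window: half-open, the first 25% of the inter-contact interval;
  the final contact, which has no successor, uses the median preceding
  interval.  Selecting exactly the k = 8 best rank-sum samples is the
  threshold-free equivalent of tuning per-signal thresholds until 8 samples
  qualify (8 ≈ 5% of a 150 ms contact at 1125 Hz).
- The standing period supplies the starting zero-velocity anchor (0.1 s
  before its end), so stride 1 — and hence cumulative distance — is measured
  from the start line.

## Attitude filter

Error-state (multiplicative) EKF with a 3-state attitude error; velocity and
position stay outside the filter because drift is corrected by the explicit
per-stride linear correction.  Propagation is the first-order quaternion
exponential of the trapezoid-averaged angular rate.  Between updates the
covariance is rotated by the relative body rotation and grows by the angle
random walk `q·Δt` with `q = (σ_gyro² + LSB²/12)·dt` by default (the
process-noise PSD is configurable; size it up when an unmodelled residual
bias is suspected).  At each zero-velocity sample the normalised specific
force observes the world up-direction (`H = [R̂ᵀu]×`, measurement σ
0.02 rad ≈ 1.1°, dominated by stance micro-dynamics rather than
accelerometer noise); the update corrects roll and pitch, yaw stays
unobservable and is irrelevant to the horizontal stride-length norm on a
straight lane.  Initial roll/pitch come from the standing-window mean
specific force, yaw = 0 by convention (the run direction defines world +x).
Drift correction is applied to all three axes.

## Integration and metrics

Trapezoidal rule for both integrations (second-order, standard in this
literature).  Within each stride the residual end velocity is removed by a
correction growing linearly in time, making velocity *exactly* zero at every
zero-velocity instant; a constant spurious acceleration is cancelled
identically, including its displacement.  Samples before the anchor and
after the last zero-velocity index carry no correction and are excluded from
metrics.  Stride length is the x–y norm of the per-stride displacement
(matching a camera's horizontal projection); stride and segment speeds
divide distance by the zero-velocity-to-zero-velocity duration, which
jitters by where within the ~150 ms stance each instant falls — visible as
stride-speed scatter even when lengths are near-exact.

Error measures are relative percentages `(calc/truth − 1)·100`; the
cumulative error is identically the length-weighted mean of the per-stride
errors.  Agreement uses Bland–Altman `bias ± 1.96·SD` (sample SD);
three-rater video readings are reconciled by relative range over the mean
with a 2% tolerance (drop the measurement farthest from the other two's
mean, else re-analyze).  Standardized-β effect bins use boundaries 0.295 and
0.495 — the conventional 0.29/0.30 and 0.49/0.50 edges leave gaps in which
no value could be classified.  The headline regression p-value is the slope
t-test (simple model) or model F-test (multiple model).

## Saturation behaviour

Gyroscope clipping removes rotation where the rate exceeds ±2000 °/s
(mid-swing at the default waveform).  The attitude estimate then lags the
true pitch, the large swing accelerations are mis-projected, and the
spurious velocity accumulated by stride end is charged to the linear drift
correction — which subtracts roughly half of it from the displacement.  The
net effect is a systematic *underestimation* of stride length that grows
with the clipped-sample fraction (≈−9% at 1.6% clipped, ≈−40% at 3.2%), while
sub-range peak rates leave errors at the noise floor.  The pitch waveform's
sign convention is chosen so clipping produces this underestimation, the
behaviour consistently reported for contact-phase gyro saturation in
sprinting.

## Numerical notes and degenerate inputs

- Problem sizes: recovery tests use the canonical 17-stride sprint
  (≈25 s × 9000 Hz internally, ≈28 k samples at 1125 Hz); multi-seed checks
  use 20 seeds, the saturation sweep 6 rate points × 2 seeds, lag recovery
  100 random offsets on a 6-stride trial.
- The finite-difference round-trip check (position ↔ specific force) is
  valid only where jerk is continuous; samples at toe-offs and landings are
  excluded from it.
- Ideal (infinite-range, unquantised, noiseless) specs short-circuit
  quantisation and clipping exactly, so statics tests are bit-exact.
- Flat inputs to the cross-correlator, windows with motion in the bias
  estimator, empty candidate masks, sub-3-sample stride intervals and
  non-positive truths all raise typed errors rather than returning numbers.
- Quaternions are renormalised every 1024 propagation steps; covariance
  divergence (non-finite) aborts with a diagnostic.

## Known limitations

- No toe-off detection, contact/swing times, foot clearance or joint-angle
  outputs; no heading aiding (curved runs would need it); no magnetometer;
  no multi-IMU support.
- The accelerometer saturation model is symmetric clipping; real sensors
  also distort near the rails, only crudely covered by the 98% guard band.
- Stride-to-truth association assumes equal counts (it raises otherwise);
  missed or spurious contacts are not automatically repaired.
- The EKF has no bias state; residual bias is handled by the standing-window
  calibration and, if needed, a larger process-noise PSD.
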