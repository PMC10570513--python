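# Methods

`imugait` estimates lower-limb kinematics and the body-weight-normalized
vertical ground reaction force (vGRF) of treadmill walking from body-worn
inertial sensors, and ships a synthetic-data generator that produces such
recordings with exact ground truth. This note documents the models, the
conventions the package commits to where the underlying method leaves a
choice open, the numerical details, and the limits of what the synthetic
experiments demonstrate.

## 1. Hinge-joint model and calibration

Each joint (hip, knee, ankle) is modeled as an ideal hinge between two
rigid segments, each carrying one IMU at an arbitrary, unknown mounting
pose. Two kinematic constraints identify the geometry from raw data
alone — no magnetometer, no assumed alignment:

* **Axis constraint.** The angular rates of the two sensors differ only
  by the joint rotation, so the projections of `g1(t)` and `g2(t)` onto
  the joint plane have equal norms: `‖g1×j1‖ − ‖g2×j2‖ = 0` for the true
  axis directions `j1`, `j2` (unit vectors in each sensor frame).
* **Center constraint.** Removing the rotation-induced acceleration
  `Γ_g(o) = g×(g×o) + ġ×o` from each accelerometer reading leaves the
  joint-center specific force, whose norm is frame-invariant:
  `‖a1 − Γ_g1(o1)‖ − ‖a2 − Γ_g2(o2)‖ = 0`.

The axes are parameterized by inclination/azimuth on the unit sphere
(4 parameters) and both sums of squared residuals are minimized with
SciPy's Trust Region Reflective least squares. The axis fit runs from
four deterministic starts — `(φ,θ) ∈ {(0,0), (0,π/2), (π/4,π),
(−π/4,−π/2)}` applied to both sensors — and keeps the lowest objective,
because the sign-invariant objective has mirror minima. A fit is refused
when the gyro-magnitude standard deviation is below 0.2 rad/s
(insufficient excitation). Angular acceleration `ġ` is obtained by
central differences (one-sided at the record ends); callers may supply
exact values when they are available (the simulator does).

**Offset convention.** Writing the sensor trajectory as
`r_i = p + R_i o_i` with `p` the joint center, the constraint above
holds when `o_i` is the *sensor origin's position relative to the joint
center, in sensor coordinates*. Only the component of `o_i`
perpendicular to the axis is physically determined: any point of the
hinge axis is a valid "center", which makes the *simultaneous* equal
shift of both offsets along their axes a null direction of the
objective. (Shifting one offset alone is *not* null — the package tests
pin this down.) The returned offsets have the axis component projected
out; each is then the perpendicular offset of its sensor from the axis,
a representation invariant along the null direction. The fit residual is
reported at the raw, on-manifold solution.

**Sign convention.** The axis constraint cannot distinguish `j` from
`−j`. `resolve_axis_sign` makes the pair unique: `j1`'s largest
component is made positive, and `j2`'s sign is chosen so the
axis-projected rates `g1·j1` and `g2·j2` correlate non-negatively. With
sensors mounted roughly anatomically this yields a consistent
flexion-positive sense across subjects; for arbitrary mounting the
recovered angle is defined up to sign.

## 2. Flexion/extension angle estimation

Two independent angle measurements are fused:

* `α_gyr(t)` — the cumulative trapezoidal integral of
  `g1·j1 − g2·j2`. Smooth and accurate over seconds, but it drifts
  without bound under gyro bias.
* `α_acc(t)` — each accelerometer reading is shifted to the joint
  center (`ã = a − Γ_g(o)`), projected onto a joint-plane basis
  `x = j×c`, `y = j×x`, and the signed angle between the two planar
  projections is taken. Drift-free but noisy, and undefined at samples
  where a projection degenerates (returned as NaN).

The angle-between-projections is direction-ambiguous as written; the
package takes the angle *from* the proximal projection *to* the distal
one, which is the sense that agrees with the gyro integral — with the
opposite order the two sources cancel instead of reinforcing in the
filter below.

The complementary filter blends them per sample:

    α(t) = λ·α_acc(t) + (1−λ)·(α(t−Δt) + α_gyr(t) − α_gyr(t−Δt))

with defaults `λ = 0.02` and `Δt = 0.016 s` (60 Hz). `α(0) = α_acc(0)`.
Because `α_acc` is only defined modulo 360°, each step uses the
representative of `α_acc` closest to the gyro-propagated prediction;
without this, noise near the ±180° branch cut injects spurious full
turns. At NaN `α_acc` samples the filter propagates by the gyro
increment alone. The filter's effective time constant is `Δt/λ ≈ 0.8 s`:
bias drift is bounded at roughly `bias·Δt/λ` (≈0.23° for 0.005 rad/s)
and accelerometer angle noise is attenuated by roughly `√(λ/2)`.

**Identifiability of the reported angle.** The hinge angle is measured
up to an overall sign (axis-sign degeneracy) and an additive constant
(the joint-plane reference `c` and the axis-alignment rotation both
shift `α_acc` by a constant; changing `c` changes `α_acc` by a
*time-constant* amount, zero exactly when `j1 = j2` numerically). In
practice the zero reference is fixed by a calibration posture.
Accordingly, angle accuracy is always evaluated after aligning sign and
constant offset against the reference; drift and noise are unaffected by
this alignment. The `c` vector defaults to the standard basis vector
most orthogonal to the axis (best conditioning).

Angular velocities are obtained by zero-phase low-pass filtering the
fused angle at 6 Hz (second-order Butterworth applied forward and
backward, effective fourth order) and differentiating by central
differences — filter-then-differentiate. Vertical trunk acceleration
uses the device orientation quaternion: the specific force is rotated to
the global frame, gravity (9.81 m/s², global Z up) is removed, and the Z
component is kept.

## 3. Gait events, cycle domain and synchronization

* **IMU contacts.** The anteroposterior hip acceleration is zero-phase
  low-pass filtered at 2 Hz; local maxima (with a prominence floor of
  10% of the filtered range and a minimum separation of 0.4× the median
  inter-peak interval) mark foot contacts. Maxima within an edge guard
  of the record boundaries are discarded — the zero-phase filter's
  transient can invent or displace peaks there; the study pipeline uses
  a 2.5 s guard, covered by warm-up strides.
* **Force contacts.** A vGRF onset is a rising crossing of 0.03 BW
  sustained for 3 samples, backtracked to the last unloaded sample (the
  instant the force starts growing); toe-off is the matching falling
  crossing advanced to the first unloaded sample. A contact lying
  exactly on a force sample is recovered exactly.
* **Matching.** The two contact lists are paired by greedy nearest-time
  matching within a quarter of the median stride period, so
  synchronization starts from the first contact both modalities saw and
  unpaired edge contacts are dropped.
* **Cycle normalization.** Each inter-contact interval is mapped onto a
  fixed 101-point 0–100% grid by linear interpolation. Strides outside
  0.5–3 s are dropped and logged. The 60 Hz kinematics and the 100 Hz
  force are each interpolated onto the grid directly; no time-domain
  resampling between rates occurs. The synchronized table assigns every
  kinematic row the vGRF at the same stride and cycle percent.

## 4. vGRF regression

Feature sets: *Kinematics* — hip/knee/ankle flexion/extension angles and
angular velocities plus cycle percent (7 inputs); *C7* — the same plus
the trunk vertical acceleration (8 inputs). Inputs are min-max scaled to
[0, 1] on the training partition only; validation and test data reuse
the training scaler and may leave [0, 1] (never clipped). The study
pipeline additionally centers each subject's angle features on their
session mean: the accel-angle's additive constant varies with mounting
and the `c` choice, and real studies remove it with an anatomical
reference posture; without centering, inter-participant errors are
dominated by these artificial offsets rather than by the method.

* **Random forest** (scikit-learn): 170 trees, depth ≤ 35, minimum
  1 sample per leaf, 2 to split, `log2` of the feature count tried per
  split, seeded.
* **Feedforward network** (in-package, numpy): input layer, five hidden
  layers of ten ReLU units, linear output; Adam on a batch-RMSE loss;
  inverted dropout after every hidden activation with a per-unit
  max-norm-4 constraint on incoming weights re-applied after each
  update; min-max-scaled inputs. Training defaults: dropout 0.05,
  learning rate 3e-3 halved every 100 epochs, batch 128, up to 400
  epochs with early stopping (patience 40) on validation RMSE, best
  weights restored, bit-reproducible for a fixed seed. The dropout rate
  is deliberately small: with 10-unit layers, rates near 0.2 inject
  enough gradient noise to cap the achievable training RMSE at roughly
  twice its value at 0.05. Even so, the 5×10 architecture converges to
  0.05–0.09 BW training RMSE depending on seed — consistent with
  published errors for networks of this size on this task — so the
  capacity test bounds the FNN at 0.10 BW and the forest (a
  near-interpolator here) at 0.05 BW.

Split protocol: two subjects are held out entirely (inter-participant
test); the remaining subjects' rows are split 80/20 uniformly at random
(unstratified) into training and intra-participant validation.

Feature relevance is the permutation importance: the mean increase in
prediction RMSE over repeated seeded shuffles of one input column on
evaluation data. All permutations for all features are drawn from a
single generator in feature order, which makes the quantity exactly
reproducible.

## 5. Evaluation metrics

Per-stride RMSE (BW) over the cycle grid; NRMSE = RMSE divided by the
range (max − min) of the *measured* vGRF, computed per reporting group;
Pearson correlation; and the characteristic peaks of the walking vGRF:
the loading peak LP (maximum over the first half of stance), the
mid-stance minimum MP (minimum strictly between LP and TP) and the
terminal-stance peak TP (maximum over the second half of stance). The
"first/second period of support" boundary is taken as the midpoint of
stance (configurable). Peak magnitude errors are reported as absolute
values; timing delays are signed, positive when the estimated peak is
late. A stance with no interior minimum (flat or monotone) raises a
diagnostic error rather than fabricating peaks.

## 6. Synthetic data

**Hinge recordings.** Two segments share an ideal hinge. Segment 1
rotates about two fixed space axes (amplitudes ≈ 0.45/0.29 rad at
0.31/0.53 Hz), the joint center translates sinusoidally (default 8 cm
amplitude on three incommensurate frequencies), and the hinge angle
follows a sinusoid or a knee-like multi-harmonic profile (default 60°,
0.9 Hz). Angular rates, angular accelerations and specific forces are
evaluated *analytically*, so both calibration constraints hold to
machine precision at the true geometry — the simulator can therefore
serve as an exact oracle. Ground truth carries the geometry, the hinge
angle in the same sense the gyro integral measures, exact `ġ`, and
noise-free signal copies. Noise model: additive white Gaussian gyro and
accelerometer noise plus a constant gyro bias per sensor (a scalar
magnitude is given a seeded random direction).

**Gait studies.** A planar (sagittal) chain — pelvis, thigh, shank,
foot — is driven by smooth periodic joint-angle splines through standard
gait control points, scaled per speed (0.85–1.15 across 1.5–4.5 km/h)
and per subject (5% scatter), with stride-period jitter (2%). Cadence
defaults to 42/47/52/57 strides/min across the four speeds. Sensor
mounts are anatomically aligned poses perturbed by up to 15°, with
per-subject segment lengths. Sensor accelerations come from spline
differentiation of the exact chain positions; the pelvis translation is
constructed so its anteroposterior acceleration peaks at each right-foot
contact, and a C7 trunk point oscillates vertically with configurable
acceleration amplitude (default 2 m/s²). The vGRF is a monotone-cubic
(PCHIP) double bump through (0,0), LP, MP, TP and (stance end, 0) —
monotone segments guarantee the configured peaks are the exact extrema —
with stance occupying 62% of the cycle, exact zeros in swing, per-speed
peak tables (LP 1.02→1.15, MP 0.95→0.72, TP 1.00→1.10 BW from slow to
fast) and 1% multiplicative plate noise in stance only. Each trial adds
two warm-up and two cool-down strides so edge-guarded detection still
delivers the configured stride count. Only the right leg is simulated;
left contacts are not present in any signal.

**What the synthetic experiments do and do not show.** They verify the
estimation machinery: that calibration recovers known geometry, that
fusion tracks a known angle under realistic noise and bias, that events,
cycle normalization and synchronization are exact where exactness is
possible, and that the regressors can learn the kinematics-to-force
mapping when one exists by construction. They do not emulate soft-tissue
artifact, left-right force sharing, non-hinge joint physiology,
magnetometer-free orientation drift of the C7 quaternion, or the
biological variability of real gait — so the study-level accuracy
figures here are sanity scales for the pipeline, not claims about
performance on human recordings.

## 7. Problem sizes and defaults

The default desk-scale study is 12 subjects × 4 speeds × 8 strides
(≈39 000 cycle rows), with per-subject, per-joint calibration from 30 s
walking-like and 30 s circling hinge recordings at the study's noise
levels. The angle-accuracy benchmark uses 60 s records at 60 Hz with
gyro noise 0.01 rad/s, bias 0.005 rad/s and accelerometer noise
0.1 m/s², scored over the final 50 s and averaged over 20 randomized
mounting geometries. These sizes were chosen so a complete run is
comfortable on a single CPU while every stage still operates well above
its excitation and sample-size floors.

## 8. Known limitations

* The reported angle's zero reference is conventional; comparisons
  across systems need a shared reference posture.
* Contact detection assumes one dominant anteroposterior acceleration
  maximum per stride (right contacts); real bilateral data requires the
  every-second-maximum convention, which the simulator does not
  exercise.
* The center fit inherits noise from the differentiated gyro; supplying
  an externally smoothed `ġ` improves it.
* The FNN's training error is seed-dependent within 0.05–0.09 BW; the
  forest dominates it on in-distribution validation data, while the gap
  narrows on held-out subjects.
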