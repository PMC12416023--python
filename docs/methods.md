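# Methods

`armkin` is a simulation and analysis framework for validating single-camera
markerless upper-limb motion capture against a marker-based reference. It
reproduces the *analysis* of such a validation study end to end on synthetic
data: scripted movements are observed by two simulated measurement channels,
joint angles are computed by two competing methods, and their agreement with
the reference is quantified with repeated-measures Bland–Altman statistics,
RMSE, and comparison ANOVAs. Because the raw recordings of such studies are
rarely public, the synthetic generator is a first-class, tested component: it
defines exactly what the pipeline is validated against.

## Kinematic model

The upper limb is a reduced rigid-body chain:

* **Thorax** — fixed; its anatomical frame is the world frame (+Y up, the
  subject faces −X, the subject's right side along −Z; right-handed).
* **Clavicle** — a rigid offset from the thorax origin to the glenohumeral
  centre. Shoulder-girdle articulation is deliberately absorbed into the
  shoulder ball joint: single-camera keypoints carry no scapular information,
  so separate clavicle/scapula degrees of freedom would be unobservable.
* **Shoulder** — 3-DOF ball joint whose generalised coordinates *are* the
  intrinsic Y-X-Y Euler angles of the thorax-to-humerus rotation: plane of
  elevation (0° = lateral/abduction plane, +90° = forward flexion plane),
  angle of elevation (0° = arm hanging, in [0°, 180°]), and axial rotation.
  IK output is therefore directly the reported clinical angles.
* **Elbow flexion** — 1 DOF about the humerus Z axis.
* **Forearm pronation** — 1 DOF about the forearm long axis; lockable. It is
  locked during IK by default and excluded from all agreement statistics,
  because with the elbow extended the pronation axis is geometrically
  indistinguishable from the shoulder axial-rotation axis (see the axis
  diagnostic below) and the thumb/hand keypoint that would disambiguate it is
  excluded by default.

Default anthropometry at scale 1: humerus 300 mm, forearm 260 mm, thorax
height 480 mm, glenohumeral centre at (0, −20, −180) mm from the thorax
origin. All dimensions scale linearly with a participant scale factor
(realistic adults ≈ 0.8–1.2). Default joint limits (config-overridable):
plane of elevation [−90°, 130°], elevation [0°, 180°], axial rotation
[−90°, 90°], elbow flexion [0°, 150°], pronation [−90°, 90°].

Virtual keypoints fixed in the segment frames: sternum and a C7 proxy
(thorax), shoulder (glenohumeral centre), elbow, wrist (midpoint of the
styloid axis), and a hand/thumb point. The wrist lies on the pronation axis,
so it is insensitive to pronation — the geometric reason pronation needs the
hand point.

### Axis-independence diagnostic

`axis_independence_test` computes the world-frame unit vectors of the six
Euler rotation axes of the two joint decompositions (shoulder Y, X′, Y″;
elbow Z, X′, Y″) and counts how many are non-parallel (|dot| < 1 − tol,
default tol = 1e−3) to every earlier axis. With the forearm aligned to the
humerus the pronation axis duplicates the axial-rotation axis, leaving five
independent axes. Two exact degeneracies are built into the geometry: at
flexion 0° (pronation ∥ axial rotation) and at flexion exactly 90° (the
elbow line-of-nodes axis ∥ the humerus long axis, |dot| = sin f). A
generically flexed configuration (e.g. 60°) separates all six.

## Movement scripts

Ten deterministic scripts, five *planar* (isolating one DOF: shoulder
abduction, shoulder flexion, elbow flexion, shoulder rotation,
pronation-supination) and five *ADL-like* multi-joint tasks (brush hair,
perineal care, collect change, drink from cup, eat with spoon). Planar
excursions use raised-cosine or sinusoidal profiles; ADL tasks are
monotone-overshoot-free PCHIP splines through documented waypoints, padded
with flat anchors so cycles join with near-zero velocity. All scripts start
and end at a seated start posture (elevation 10°, elbow 5°; the two
rotation tasks start with the elbow flexed 90° per their protocol), stay at
least 1° inside every joint limit, and keep shoulder elevation ≥ ~5° so no
frame enters the Euler gimbal band. The default cycle is 4 s ("slow pace"),
repeated 3 times per trial; shoulder flexion gets a doubled cycle because it
is two movements (forward raise plus backward extension) with a slow sweep of
the elevation plane between them. Peak amplitudes are parameters with
documented defaults (e.g. abduction peak 150°).

## Measurement simulation

* **Reference channel** (default 120 Hz): forward-kinematics keypoints plus
  isotropic Gaussian noise (default sd 0.3 mm, optical-marker quality).
* **Markerless channel** (default 30 Hz): a sample stamped `t` reports the
  body state at `t − latency` (default latency 0.15 s); keypoints get
  Gaussian noise (default sd 8 mm) inflated along the camera viewing axis by
  a placement-dependent depth multiplier (frontal 2.0 along −X, sagittal 1.4
  along −Z); segment orientations get small random rotations (rotation-vector
  components i.i.d. normal; default sd 2.5°, × 1.3 frontal) and constant
  per-segment *device-convention* frame offsets (axis-permutation rotations
  post-multiplying the true orientation); each keypoint is independently
  misdetected with probability 0.01 per frame, flagged invalid and displaced
  by sd-150 mm noise.

These magnitudes are configurable study conditions chosen to be plausible for
a consumer depth camera, not calibrated estimates of any specific device. The
generator does **not** emulate soft-tissue artifact, systematic
pose-estimator biases that correlate with posture, or occlusion that depends
on the actual arm geometry — so passing tests demonstrate correctness of the
pipeline and realistic orders of magnitude, not device-level fidelity.

## Angle computation

**Coordinate-frame (CF) method** (orientation stream): optional first-order
exponential smoothing on the rotation manifold
(`q̂_t = slerp(q̂_{t−1}, q_t, α)`, default α 0.5 in the pipeline, α = 1
disables; a windowed geodesic mean would be the natural alternative) →
quaternions to matrices → post-multiplication by the inverse device offsets
(realignment) → joint rotations `R = R_proximalᵀ R_distal` → intrinsic Euler
decomposition (shoulder Y-X-Y; elbow Z-X-Y, flexion leading) → unwrapping
(period 360°) → cubic-spline upsampling to 120 Hz. Frames whose elevation is
within 1° of the gimbal band are flagged; at exact gimbal lock the third
angle is set to zero and the first carries the free sum.

**Inverse-kinematics (IK) method** (keypoint stream): the template model is
scaled so humerus/forearm lengths equal the medians of the observed
shoulder–elbow and elbow–wrist distances (remaining dimensions by the mean
ratio); invalid samples are linearly interpolated, then all coordinates are
low-pass filtered (fourth-order zero-phase Butterworth, 5 Hz at 30 Hz
markerless, 8 Hz at 120 Hz reference; odd-reflection padding of 3 × order);
each frame's pose solves

    min_q  Σ_m w_m ‖k_m(q) − y_m‖²  +  λ ‖q − q_prev‖²,   q within joint limits

by damped Gauss–Newton with the analytic kinematic Jacobian
(∂k/∂q_i = a_i × (k − o_i)), bound clipping, and warm starting from the
previous frame. The first resolved frame starts from a closed-form geometric
estimate inverted from its elbow/wrist positions (elevation and plane from
the upper-arm direction, flexion and axial rotation from the forearm
direction in the humerus frame); a fixed neutral start can strand the whole
warm-start chain in a wrong local minimum when a trial begins far from
neutral, e.g. the elbow-flexed-90° start of the rotation tasks. Weights are equal by
default, zero for invalid points and for the excluded hand/thumb point. The
proximal term (λ = 1e−6 mm²/deg²) is numerically negligible against
millimetre-scale residuals but pins the plane-of-elevation/axial-rotation
split where elevation ≈ 0 makes it indeterminate; the reported objective
excludes it. Termination: gradient < 1e−10, squared step < 1e−16, or
objective < 1e−14; only cost-decreasing steps are accepted, so the objective
is non-increasing over iterations. Frames with fewer than three usable
keypoints, or with neither elbow nor wrist usable, are marked unresolved and
linearly interpolated from the nearest resolved frames; a trial with > 10%
unresolved frames is excluded from the analysis with a logged count. Angles
are computed at the native 30 Hz and upsampled to 120 Hz afterwards. A
compiled (numba) kernel executes this loop; a pure-Python reference
implementation of the same algorithm is retained and tested to agree with it.

**Reference angles** use the same IK machinery at 120 Hz with the 8 Hz filter
and no resampling.

## Synchronisation and differences

A single integer lag per trial and method is estimated by normalised
cross-correlation (window ±2 s) of the mean-removed angle channel with the
largest excursion shared by both tables — the angle of elevation in most
tasks. Ties (periodic signals) resolve to the smallest |lag|. If no channel
moves more than 0.5° (the pronation-supination task holds all four analysed
angles nominally constant) the lag is indeterminate and set to 0, which is
also irrelevant: there is no excursion to misalign. Positive lag means the
test stream is delayed relative to the reference. After alignment, per-frame
differences (test − reference) over the common support are pooled across the
three repetitions and grouped by participant; frames gimbal-flagged in either
table are dropped. The four analysed angle sets are plane of elevation, angle
of elevation, shoulder rotation and elbow flexion-extension.

## Agreement statistics

For each difference set a one-way ANOVA with participant as the factor gives
`MS_participant = SS_between/(k−1)` and `MS_residual = SS_within/(N−k)`;
the between-participant variance is `max(0, (MS_p − MS_r)/n̄)` with
`n̄ = N/k` (reading "average observations per participant" literally; the
unbalanced-ANOVA constant `n₀ = (N − Σnᵢ²/N)/(k−1)` is available as
`nbar_mode="anova_n0"`), total variance is their sum, and SD its square
root. Bias is the grand mean of the pooled differences (for balanced designs
identical to the mean of participant means), the 95% limits of agreement are
bias ± 1.96 SD, and RMSE = √MS_residual (within-participant variability).
Negative between-variance is clamped to zero, standard variance-components
practice.

Four planned one-way ANOVAs at α = 0.05 (no multiple-testing correction)
compare mean RMSE between methods within each plane and between planes within
each method, using the 40 per-plane-per-method RMSE values (10 movements × 4
angle sets); effect size is partial eta-squared with Cohen's
`f = √(η²ₚ/(1−η²ₚ))`. P-values come from the upper tail of the F
distribution.

The `simulate_difference_set` helper generates Gaussian difference data with
known bias and variance components; with `standardize=True` the draws are
rescaled to their exact target sample moments so estimator tests check the
algebra rather than sampling luck of a particular seed.

## Experiment orchestration

The default configuration mirrors the study design: 12 participants (scales
uniform in [0.9, 1.1]), 10 movements, 2 camera placements, 3 repetitions,
120/30 Hz — giving 80 difference sets per method (2 × 10 × 4) and 40 pooled
RMSE values per plane per method. Per-trial randomness derives from
`SeedSequence(master_seed, participant, movement, placement, stream)`, so a
configuration and seed reproduce every output byte for byte. The report
aggregates bias (SD), LoA bounds and RMSE by plane × angle type × task type
(All Tasks / Planar / ADL), with an "Average" angle row pooling the four
angle sets. Results are written as CSV (full `%.17g` precision; re-read them
with `read_result_csv` for exact round trips) and a JSON summary of the four
comparison ANOVAs.

## Numerical choices and degenerate inputs

* Quaternions are stored `[w, x, y, z]`, canonicalised to `w ≥ 0`; SLERP
  takes the shortest arc and falls back to normalised linear interpolation
  below 1e−10 rad.
* Rotation-centre estimation (`estimate_rotation_center`) is the linear
  shared-centre sphere fit: `2 p·c − d_m = |p|²` solved jointly for the
  centre and per-marker radius terms; rank deficiency (e.g. static frames) is
  detected from the singular-value ratio at 1e−9. Pure translations that
  happen to be well-conditioned are not specially detected; the reported RMS
  radius residual is the practical quality check.
* Butterworth `FilterSpec.order` is the *single-pass* order; forward-backward
  application squares the magnitude response.
* Upsampling is restricted to integer rate ratios; scalar channels use cubic
  splines (exact at coincident samples), orientations segment-wise SLERP.
* Problem sizes in the test suite and acceptance script (participant counts
  of 2–12, the 100-fixture statistics oracle, 10,000-rotation round-trip)
  were chosen so the full validation completes in a few minutes on one core
  while keeping every structural count of the full design intact.

## Known limitations

* The thorax is fixed: trunk sway and scapulothoracic rhythm are not
  simulated, and the IK base frame is assumed known.
* The noise model is temporally white; real pose estimators produce
  temporally correlated, posture-dependent errors.
* Sub-sample lag refinement is not implemented; synchronisation is exact only
  when the true latency is a multiple of the common sample period.
* The CF and IK methods share the simulator's forward kinematics as ground
  truth; agreement on synthetic data therefore validates internal
  consistency, not the anatomical fidelity of any real device.
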