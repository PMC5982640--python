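# Methods

This note records the models and procedures `rehabmotion` implements, the
defaults it ships, the choices that were genuinely open, and what the
synthetic world does and does not establish.

## Feature representation

Skeletal frames use the 25-joint depth-camera vocabulary (positions in
meters, camera coordinates; per-joint orientation quaternions in
(w, x, y, z) order; floor plane `ax + by + cz + d = 0`). The informal
clinical names map onto it: "shoulder center" is `spine_shoulder`, "hip
center" is `spine_base`. When a file carries no floor plane, the horizontal
plane through the lower ankle is used as a fallback.

**Personal coordinate system (PCS).** Per frame, the left-to-right hip
vector projected onto the floor plane gives the lateral axis, the floor
normal (oriented toward the body) the vertical axis, and their cross
product the sagittal axis; the origin is the floor point below the hip
midpoint. All positional features are expressed in this frame, which makes
them invariant to rigid rotations about the floor normal and translations
along the floor (verified to 1e-6 in the tests). A consequence worth
knowing: a translation of the pelvis itself is unobservable in PCS
coordinates (the frame moves with the hips), so the signed lateral
channels used for drift detection measure motion **relative to the stance
ankle**.

**Angles** come from the cosine law on inter-joint distances,
`cos A = (-a² + b² + c²) / (2bc)`, in degrees. The frontal hip angle is
the elevation of the hip→knee vector from the downward vertical after
projection onto the frontal (lateral–vertical) plane; it equals the
abduction angle of a straight leg.

**Buffered speeds.** Per-frame velocities are averaged over a sliding
buffer of 15 frames (0.25 s at the nominal 60 Hz; the length scales as
`round(0.25 × frame_rate)`). The default mode averages the velocity
vectors and reports the magnitude of the average, which is what makes the
buffer a denoiser: averaging speed *magnitudes* instead (available as
`average="magnitude"`) preserves a positive jitter floor of the order of
the per-frame noise and was measured to bury the trunk-sway signal
entirely. Angular speed is the buffered first difference of the angle
channel, kept signed. Buffered estimates lag the instantaneous signal by
about half a buffer; all pipeline statistics either compare two equally
buffered signals or tolerate the common lag.

**Trunk model features.** The published trunk model pairs shoulder-center
and hip-center speed with 3 states. Bound to unsigned speed magnitudes the
decomposition is unidentifiable — an unsigned sway has two levels (quiet /
moving), so the third state inevitably models sensor noise and the decoded
path fragments. The signed lateral sway has exactly three levels (sway
out / quiet / sway back), matching the 3-state count, and the published
trunk-velocity plots are signed; the canonical registry therefore binds
the trunk model to the signed lateral speeds of shoulder center and hip
center relative to the stance ankle. This also makes the trunk model
*directional*: low-likelihood windows can be attributed a left/right
label by comparing the observed mean of each signed channel against the
decoded state's emission mean.

## HMM core

Diagonal-covariance Gaussian emissions; ergodic transition topology.
Forward/backward run in scaled space and Viterbi in log space (numba
kernels, exact to ~1e-12 against exhaustive path enumeration; no
underflow up to 1e5 frames). Viterbi ties break toward the lower state
index. Baum–Welch sums sufficient statistics over sequences; iteration
stops when the log-likelihood gain drops below 1e-4 (max 200 iterations).
Initialization reflects the phase semantics of the states: emission
parameters from temporal quantile slices of each sequence, the initial
distribution concentrated on state 0, sticky transitions (0.9
self-probability). Variances are floored at 1e-6; a state claiming fewer
than one expected frame is re-seeded at a random data point (the only use
of the seed — fits are otherwise deterministic). Because flooring and
re-seeding make the M-step a constrained maximizer, a marginal
log-likelihood decrease is possible in degenerate fits; it is treated as
convergence so the reported trace is non-decreasing.

After fitting, states are relabelled into temporal-phase order: the rest
state is the one holding the mass at the start of the sequences, the rest
follow their mean frame-time centroid. (Ordering by first Viterbi visit
is noise-fragile and was observed to flip between training folds, which
silently corrupts any cross-fold aggregation of state statistics.)

State-count selection uses cross-validated BIC, `k ln N − 2 ln L` with
`k = (n−1) + n(n−1) + 2nd` free parameters, scored on held-out folds and
averaged. On data drawn from an HMM the scan recovers the generating
count; on raw kinematic ramps additional states keep subdividing the
continuous transitions, so the count remains a user-set parameter with
BIC as guidance.

## Assessment blueprint

Each registry entry (model + feature binding) is scored per trial:

* **Window likelihoods.** Per-frame-normalized forward log-likelihood of
  60-frame windows at stride 15. The *flag* statistic is the trial's dip —
  minimum window minus median window — which cancels subject-level
  offsets; a trial flags `low_likelihood` when its dip is deeper than any
  calibration trial's dip with 25% slack.
* **Decoding.** The Viterbi path is computed with decode-time variance
  flooring (each state variance at least 10% of the feature's signal
  variance): hard state assignment is brittle when a small cohort
  under-samples between-subject variability, and flooring at decode time
  robustifies the boundaries without perturbing the EM optimum or the
  sharp likelihood scores. Decoded paths are cleaned by evidence
  qualification — a non-rest excursion is kept only if it accumulates
  ≥ 100 nats of emission log-odds against the rest state (a genuine phase
  visit accumulates hundreds, a boundary-noise run far less) — and then
  smoothed by absorbing runs shorter than 15 frames (0.25 s).
* **Transition anomalies.** A reference profile over the calibration
  paths records per-state visit counts (merging same-state runs separated
  by < 0.5 s: a split bump is one excursion) and visit durations, the
  state-over-time occupancy in 24 normalized-time bins, and the consensus
  phase order. A trial flags `extra_transition`/`missing_transition` when
  a visit count leaves the observed range (±1 visit slack;
  `visit_slack=0` gives strict counting), `elongated_state`/
  `shortened_state` when a duration leaves the range with 25% slack
  (checked only for states whose calibration durations agree within a
  factor of 3 — no norm, no check), and `extra_transition` when the
  in-movement visit sequence returns to an earlier phase or when the
  trial occupies a state at a point of the movement where correct
  executions never are (mean occupancy < 0.02 over at least 30 frames,
  short usual gaps bridged). The occupancy and order checks are confined
  to the movement window taken from the hip model's path.
* **Timing ratios.** The published per-trial metrics are computed as
  defined: the movement clip anchors on the two opposite-signed sway-bump
  extrema (half-amplitude widths recover the phase durations of a
  raised-cosine profile; the peak is the midpoint of the near-zero
  stretch between the bumps), symmetry = time-to-peak / time-to-return,
  and synchronicity = (trunk end − m)/(m − trunk start) with m the hip
  hold midpoint, so values < 1 mean the trunk moved early. Ratios above 1
  are reported with their reciprocal; averages use the
  orientation-invariant normalized form min(r, 1/r). These reported
  ratios scatter substantially on clean trials (σ ≈ 0.2–0.3, comparable
  to the published per-trial tables), so *flags* use tighter
  self-normalizing statistics instead: movement-profile symmetry from the
  frontal hip angle (5%/95% amplitude crossings; threshold 0.8, the
  typical accepted-trial level) and trunk–hip timing from the
  cross-correlation lag between sway speed and hip angular speed mapped
  onto the hip-path landmarks (threshold 0.7, between the clean tail and
  the injected-shift level).
* **Outcome.** good if no flags and every model's minimum window
  likelihood reaches the good threshold; fair with at most one flag above
  the fair threshold; bad otherwise. Thresholds are the 25th/5th
  percentiles of the calibration distribution of per-trial minimum window
  likelihoods.

**Calibration is out-of-sample.** Thresholds and reference profiles
stored with fold *s* must describe how correct executions of *unseen*
subjects score. Each subject's correct trials are scored under its own
leave-one-subject-out registry (held out there by construction), and fold
*s* aggregates the statistics of every subject except *s*. In-sample
calibration was measured to flag entire unseen subjects.

Training uses the correct trials of a subject's peers, where "correct"
means a strict majority of raters labelled all three aspects (range of
motion, coordination, compensation) good.

## Synthetic world

The generator emulates standing right-leg hip abduction: a raised-cosine
abduction profile (rest 1 s, raise 1.5 s, hold 1 s, return 1.5 s, rest
1 s at 60 Hz; peak 40°), a trunk counter-sway of 3 cm following the angle
profile (two speed bumps of ~3 cm/s, the published magnitudes are of this
order), fixed limb lengths, and quaternions consistent with the leg
rotation. Measurement noise is band-limited: white noise smoothed over
0.25 s with stationary σ = 2 mm, approximating the temporal correlation
of skeletal-tracking jitter (frame-independent noise at that amplitude
would dominate finite-difference speeds, which real tracking does not).
Subjects differ by tempo (±15%), peak angle (σ = 3°), sway amplitude and
rest durations; trials add ±5% jitter.

Fault classes and default magnitudes: trunk sway shifted ±30 frames
(incoordination), return slowed ×1.5 (asymmetry), a 4 cm lateral jolt at
mid-hold (balance wobble, the "extra bump"), a 6 cm leftward pelvis drift
over the return (adduction compensation), and peak angle ×0.5 (reduced
range of motion). Auto-labels downgrade the corresponding aspect to
fair/bad by magnitude.

What a green test establishes: the pipeline separates these five fault
classes from clean executions across seeds (100% detection, ≤ 10% false
flags over eight evaluated cohorts) **within this stated world** — smooth
raised-cosine kinematics, stationary band-limited noise, one fault per
trial, no occlusions, no clothing artefacts, no skeleton-tracking
failures. Real patient data adds all of those; the cohort results here
bound the method's behaviour under the model's own assumptions, not its
clinical accuracy.

## Known limitations

* Only the hip-abduction kinematics are modelled; other exercises are
  id-presets of the same trajectory family.
* The two canonical models (trunk, right-hip-frontal) are the only slots
  shipped with feature bindings; the remaining slots of the ten-model
  blueprint are registry-configurable but undefined here.
* The reported (clip-based) timing ratios carry a ~half-buffer lag and
  broad scatter; they are descriptive, not decision statistics.
* Semi-Markov (explicit duration) modelling, mixture emissions and
  force/effort assessment are out of scope.
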