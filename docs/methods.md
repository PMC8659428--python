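# Methods

This note records the models, numerical choices and open design decisions
behind `comtrack`, and what the synthetic validation does and does not
demonstrate about real data.

## Pipeline model

The analysis treats two simultaneous measurements of the same latent
trajectory — the whole-body centre of mass (COM) of a person performing a
balance task:

1. an optical system observes rigid marker clusters on 11 body segments;
2. a pelvis-mounted 6-DOF tracker reports a single position in the game
   engine's coordinate frame.

**Pose estimation.** Per frame and segment, the rigid pose minimises the
marker fit error `Σᵢ ‖R·localᵢ + t − observedᵢ‖²` subject to `R ∈ SO(3)`.
The closed-form solution uses the SVD of the 3×3 marker cross-covariance
(Kabsch), with the determinant-correction that excludes reflections.
Frames with fewer than three observed markers are flagged missing;
collinear observed markers (pose unidentifiable) raise an error naming the
frames. The solver is vectorised over frames (batched SVD), so full trials
solve in milliseconds.

**COM composition.** `COM(t) = Σₛ mₛ (Rₛ(t) cₛ + tₛ(t))` with mass
fractions `mₛ > 0, Σ mₛ = 1` and segment-frame COM offsets `cₛ`. The
default 11-segment table (head, thorax+abdomen, pelvis, merged arm, thigh,
shank, foot per side) adapts de Leva-style adjusted segment-inertia
fractions; it is user-overridable via CSV. No claim is made that it
numerically matches any commercial software's segmental model — the
pipeline is validated by generator round-trip (below), not by reproducing
a proprietary COM.

**Missing-frame policy.** A missing segment frame propagates to the COM
frame; a trial with any missing COM frames is treated as COM-missing in
full. This mirrors practice, where segment occlusion prevents whole-body
COM for the trial; partial-trial analysis is deliberately not attempted.

**Registration.** The engine→lab mapping is a signed axis permutation plus
fixed translation. The default assumes a left-handed y-up engine frame and
the lab convention X forward, Y left, Z up: `lab = (engine_z, −engine_x,
engine_y)`. Signed permutations are isometries and invert exactly. The
mapping is configurable; only its form (permutation-with-signs) is fixed.

**Temporal alignment.** Both streams carry the time of one shared event
(game start) on their own clocks. The tracker stream is shifted by the
event-time difference and both streams are linearly interpolated onto a
uniform grid at the mocap rate, phase-locked to the mocap samples and
restricted to the overlap. No cross-correlation lag search and no
clock-drift correction are attempted: the protocol provides a hard event.

**Smoothing and de-trending.** Savitzky–Golay per axis. The emulated
protocol specifies a "40-point" window at 100 Hz; SG filters need an odd,
symmetric window, so the default is the nearest odd length, 41 samples
(≈0.4 s). Polynomial order is unspecified in the protocol; the default is
3, the conventional choice for position data. Edges use mirror padding.
"DC offset removal" is implemented as per-axis mean subtraction (not
first-sample subtraction): the RMS then measures waveform disagreement
rather than the static lever-arm between pelvis fixture and COM, which is
the comparison a constant-offset-tolerant proxy validation needs.

**Order of operations** is registration → alignment → smoothing → DC
removal. Aligning on raw event timestamps is exact, and the SG filter
commutes with grid-commensurate shifts, so this is equivalent to filtering
first; the order is configurable at the pipeline level.

**Metrics.** Per-axis RMS in cm (streams processed in metres, converted
only at reporting); displacement range = max − min per horizontal axis,
reported for the five standing tasks per method. Task summaries use the
sample (n−1) SD. The headline aggregate pools all analysed trial-axis RMS
values into one mean ± SD; pooling axes first and trials first differ, and
the pooled trial-axis definition is the canonical one here.

**Statistics.** The method comparison collapses the subject × task ×
method design to a per-subject paired contrast: within each subject,
tasks with both methods present are averaged per method (complete-case).
The classical test is the subject-blocked repeated-measures ANOVA computed
from sums of squares, F on (1, n−1) df (identically the squared paired t);
zero error variance with a nonzero effect reports F = +∞. The Bayes
factor integrates the noncentral-t likelihood of the paired t statistic
over a Cauchy(0, r) prior on the standardised effect (JZS), by adaptive
quadrature at relative tolerance 1e-8, split at the prior mode and the
effect MLE so the integrator sees the mass. The default scale r = 0.5
follows the common fixed-effect ANOVA default; it is configurable, and no
claim of numeric equality with any GUI package's model-averaged BF is
made. A full two-factor (method × task) Bayesian model is out of scope;
the paired-contrast collapse is the documented model choice. Evidence
labels follow the Lee–Wagenmakers bands (cuts at 1, 3, 10, 30, 100 and
reciprocals).

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes — it is
the test harness, not a biomechanical simulation.

* **Design:** 13 participants × 12 tasks at 100 Hz. Standing eyes-open
  runs 120 s and eyes-closed 30 s (protocol values); the remaining task
  durations are unspecified by the protocol and default to 10–30 s.
  A `duration_scale` shrinks all durations proportionally (floored at a
  minimum) for desk-scale runs; motion profiles are expressed relative to
  trial duration, so scaling preserves their shape. Tests and the
  acceptance script use scales of 0.05–0.25; all design counts are
  duration-independent.
* **Quiet stance** (standing, sitting, narrow, tandem, one-leg,
  eyes-closed): per axis, a sum of 2–4 sinusoids drawn from the 0.1–1.0 Hz
  physiological sway band plus low-pass-filtered Gaussian noise, with the
  deterministic amplitudes summing to the task's amplitude parameter.
  Harder stances get larger mediolateral amplitudes (narrow 3.0 cm >
  tandem 2.6 cm > one-leg 1.8 cm > eyes-closed 1.1 cm > feet-apart
  0.8 cm), mirroring the difficulty ordering of instrumented balance
  data.
* **Transitions** (sit-to-stand, reach, pick-up, look-over-shoulder) use
  minimum-jerk profiles (`10τ³ − 15τ⁴ + 6τ⁵`), the standard smooth
  primitive in motor control; the 360° turn traces a circular pelvis path
  of configurable radius with a minimum-jerk yaw profile, so its
  horizontal ranges are exactly one diameter.
* **Articulated consistency.** Segment COM points are placed at nominal
  anatomical offsets from the trajectory plus per-segment sinusoidal
  wiggle, then re-centred by subtracting the mass-weighted surplus so the
  composition identity holds *exactly* per frame; marker observations are
  the exact rigid images of the cluster geometry under each segment's
  pose. Recomposing COM from the generated markers therefore reproduces
  the stored ground truth to ~1e-15 m — the round-trip oracle used
  throughout the tests.
* **Tracker error model:** `tracker = g ⊙ (COM − mean) + mean + offset +
  noise`, in the engine frame, on a clock started a grid-commensurate
  0.2–1.0 s after the mocap clock. Defaults: sway gain (1.15, 1.15, 1.05)
  — pelvis trajectories magnify COM displacement, and observed
  standing-task range ratios sit near 1.1–1.15; lever arm (0.01, 0,
  −0.08) m; noise SD 2 mm per axis (consumer lighthouse-tracking jitter);
  no dropout. Sleep-mode dropout, when enabled, hard-truncates the
  tracker stream after the configured stationary time.
* **Missingness:** 21 COM-missing and 8 tracker-missing trials, disjoint,
  spread over exactly 10 of 13 participants; which trials are affected is
  not specified by the emulated study and is drawn pseudo-randomly from
  the seed, with every affected participant losing at least one trial.
  Missing trials stay enumerated with ground truth retained.
* **Determinism:** every trial derives an independent seed stream from
  `(study seed, participant, task)`; identical configs yield
  byte-identical datasets and output tables.

**What passing tests show — and don't.** The synthetic body is a
small-segment kinematic skeleton with sinusoidal limb motion; it has no
muscle or joint dynamics, no force-plate physics, no marker-labeling
errors, soft-tissue artefact or nonlinear tracking distortion, and its
sensor noise is white. Green tests therefore certify the *pipeline
algebra* — pose recovery, composition, registration, alignment,
filtering, metrics and inference behave exactly as specified under known
ground truth — not that a real pelvis tracker tracks a real COM to any
particular accuracy. The emulated study's human-data results are not
reproducible from synthetic data and are not targets.

## Numerical choices

* Pose SVD: reflection corrected via `det(VUᵀ)`; collinearity threshold
  1e-10 (relative) on the second singular value.
* Time base: uniform within 1e-6 s jitter; alignment grid phase-locked to
  the mocap stream; linear interpolation.
* Mass fractions validated to Σ = 1 within 1e-9; COM round-trip asserted
  at 1e-9 m.
* ANOVA degenerate case: error mean square below 1e-12 of total SS (per
  df) is treated as zero.
* BF quadrature: SciPy adaptive quadrature, relative tolerance 1e-8,
  integration split at 0 and at t/√n.
* CSV round trip: floats written at full repr precision and parsed with
  pandas' round-trip parser.

## Known limitations

* The anthropometric default is a merged 11-segment table; per-subject
  scaling (height/mass regression) is not implemented.
* Only the event-based alignment of the emulated protocol is provided; no
  automatic lag estimation.
* The Bayesian model is the paired-contrast JZS BF; the full multi-factor
  model space (random-slope structures, model averaging) is out of scope.
* Displacement "area" is the per-axis max − min range, not a 2-D sway
  area; Bland–Altman limits and ICC are not computed.
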