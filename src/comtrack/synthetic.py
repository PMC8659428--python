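"""Synthetic balance-study generator with full ground truth.

Emulates the measurement setting the analysis pipeline assumes: 13
participants perform 12 balance tasks (the clinical balance-battery subset
feasible in a head-mounted-display environment) at 100 Hz, instrumented
simultaneously by

* an optical system observing rigid marker clusters on eleven body
  segments, from which whole-body COM is composed, and
* a pelvis-mounted 6-DOF tracker whose position imperfectly proxies the
  COM: a rigid lever-arm offset, a per-axis sway gain (pelvis motion
  magnifies COM motion), additive white measurement noise, and an optional
  sleep-mode dropout that truncates the stream.

Quiet-stance tasks synthesise postural sway as a sum of 2-4 low-frequency
sinusoids (0.1-1.0 Hz, the physiological sway band) plus band-limited
noise; transitions (sit-to-stand, reach, pick-up) follow minimum-jerk
displacement profiles; the 360-degree turn traces a circular pelvis path.
Segment marker data are constructed so that recomposing the COM from the
generated clusters through the kinematics module reproduces the stored
ground-truth COM to machine precision.

The default missing-data pattern removes the COM stream from 21 trials and
the tracker stream from 8 disjoint trials, spread over exactly 10 of the
13 participants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .body import DEFAULT_MARKER_LOCAL, AnthropometricModel, default_anthropometric_model
from .errors import ConfigurationError, ValidationError
from .kinematics import MarkerClusterSet
from .preprocess import ENGINE_TO_LAB, AlignmentEvent, FrameMapping
from .timeseries import TimeSeries3D

MOTION_PRIMITIVES = (
    "quiet_sway",
    "sit_to_stand",
    "sit_quiet",
    "reach_forward",
    "pick_up",
    "look_over_shoulder",
    "turn_360",
    "alternate_step",
    "tandem_sway",
    "one_leg_sway",
    "narrow_sway",
    "eyes_closed_sway",
)

_SWAY_PRIMITIVES = {
    "quiet_sway",
    "sit_quiet",
    "tandem_sway",
    "one_leg_sway",
    "narrow_sway",
    "eyes_closed_sway",
}

#: the five standing tasks on which displacement ranges are compared
STANDING_TASK_IDS = (2, 4, 5, 11, 12)

TASK_NAMES = {
    1: "Sitting to standing",
    2: "Standing unsupported",
    3: "Sitting unsupported",
    4: "Standing with eyes closed",
    5: "Standing with narrow base of support",
    6: "Reaching forward",
    7: "Picking up object",
    8: "Looking over shoulder",
    9: "Turning 360 degrees",
    10: "Placing alternate foot on stool",
    11: "Tandem stance",
    12: "One leg standing",
}

_BASE_STAND = np.array([0.0, 0.0, 0.95])
_BASE_SIT = np.array([0.05, 0.0, 0.55])

#: nominal segment-COM offsets from the whole-body COM while standing (m)
_SEGMENT_LAYOUT = {
    "pelvis": (0.0, 0.0, 0.0),
    "thorax": (0.0, 0.0, 0.35),
    "head": (0.0, 0.0, 0.65),
    "arm_l": (0.0, 0.25, 0.30),
    "arm_r": (0.0, -0.25, 0.30),
    "thigh_l": (0.0, 0.09, -0.35),
    "thigh_r": (0.0, -0.09, -0.35),
    "shank_l": (0.0, 0.10, -0.70),
    "shank_r": (0.0, -0.10, -0.70),
    "foot_l": (0.05, 0.10, -0.92),
    "foot_r": (0.05, -0.10, -0.92),
}

#: per-segment wiggle amplitude (m) and rotational amplitude (rad)
_SEGMENT_WIGGLE = {
    "pelvis": (0.004, 0.05),
    "thorax": (0.008, 0.08),
    "head": (0.010, 0.15),
    "arm_l": (0.040, 0.20),
    "arm_r": (0.040, 0.20),
    "thigh_l": (0.010, 0.08),
    "thigh_r": (0.010, 0.08),
    "shank_l": (0.012, 0.08),
    "shank_r": (0.012, 0.08),
    "foot_l": (0.008, 0.05),
    "foot_r": (0.008, 0.05),
}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TaskSpec:
    """One balance task's motion recipe.

    ``amplitude`` is in metres per lab axis (X forward, Y left, Z up). For
    sway primitives it is the peak amplitude of the deterministic sway
    component per axis; for transitions, the displacement extent; for
    ``turn_360``, ``amplitude[0]`` is the radius of the circular pelvis
    path. ``sway_band`` is the sway frequency band in Hz.
    """

    task_id: int
    motion_primitive: str
    duration_s: float
    amplitude: tuple[float, float, float]
    sway_band: tuple[float, float] = (0.1, 1.0)
    n_sway_components: int = 3
    sway_noise_frac: float = 0.2
    name: str = ""

    def __post_init__(self) -> None:
        if self.motion_primitive not in MOTION_PRIMITIVES:
            raise ConfigurationError(f"unknown motion primitive {self.motion_primitive!r}")
        vals = (self.duration_s, *self.amplitude, *self.sway_band, self.sway_noise_frac)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"task {self.task_id}: non-finite parameter")
        if self.duration_s <= 0:
            raise ConfigurationError(f"task {self.task_id}: duration must be positive")
        if any(a < 0 for a in self.amplitude):
            raise ConfigurationError(f"task {self.task_id}: amplitudes must be >= 0")
        lo, hi = self.sway_band
        if not (0 < lo <= hi < 50):
            raise ConfigurationError(
                f"task {self.task_id}: sway band must lie within (0, 50) Hz"
            )
        if not 1 <= self.n_sway_components <= 4:
            raise ConfigurationError("n_sway_components must be in 1..4")
        if not 0 <= self.sway_noise_frac < 1:
            raise ConfigurationError("sway_noise_frac must be in [0, 1)")


@dataclass(frozen=True)
class SensorErrorModel:
    """How the pelvis tracker deviates from the true COM.

    tracker = sway_gain * (COM - mean(COM)) + mean(COM) + constant_offset
              + white noise,
    truncated at ``dropout_after_s`` of stream time if set (sleep mode).
    """

    constant_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sway_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dropout_after_s: float | None = None

    def __post_init__(self) -> None:
        vals = (*self.constant_offset, *self.noise_sd, *self.sway_gain)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite sensor error parameter")
        if any(s < 0 for s in self.noise_sd):
            raise ConfigurationError("noise_sd must be >= 0 componentwise")
        if any(g <= 0 for g in self.sway_gain):
            raise ConfigurationError("sway_gain must be > 0 componentwise")
        if self.dropout_after_s is not None and self.dropout_after_s <= 0:
            raise ConfigurationError("dropout_after_s must be positive or None")

    @classmethod
    def identity(cls) -> "SensorErrorModel":
        return cls()

    @classmethod
    def default(cls) -> "SensorErrorModel":
        return cls(
            constant_offset=(0.01, 0.0, -0.08),
            noise_sd=(0.002, 0.002, 0.002),
            sway_gain=(1.15, 1.15, 1.05),
            dropout_after_s=None,
        )


@dataclass(frozen=True)
class MissingnessPlan:
    """Which (participant, task) trials lose which stream."""

    com_missing_trials: frozenset = frozenset()
    tracker_missing_trials: frozenset = frozenset()

    def __post_init__(self) -> None:
        both = set(self.com_missing_trials) & set(self.tracker_missing_trials)
        if both:
            raise ConfigurationError(f"trials in both missingness sets: {sorted(both)[:5]}")

    def validate_against(self, n_participants: int, task_ids: set[int]) -> None:
        for p, t in set(self.com_missing_trials) | set(self.tracker_missing_trials):
            if not (1 <= p <= n_participants) or t not in task_ids:
                raise ValidationError(f"missingness plan references unknown trial ({p}, {t})")

    @property
    def participants_affected(self) -> set[int]:
        return {p for p, _ in self.com_missing_trials} | {
            p for p, _ in self.tracker_missing_trials
        }


@dataclass(frozen=True)
class StudyConfig:
    """Full design of one synthetic study."""

    n_participants: int
    task_specs: tuple
    sensor_error: SensorErrorModel
    missingness: MissingnessPlan
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        ids = [s.task_id for s in self.task_specs]
        if len(self.task_specs) != 12 or len(set(ids)) != 12:
            raise ConfigurationError("exactly 12 task specs with unique task_ids required")
        self.missingness.validate_against(self.n_participants, set(ids))

    @classmethod
    def default(
        cls,
        seed: int = 0,
        duration_scale: float = 1.0,
        min_duration_s: float = 8.0,
        sensor_error: SensorErrorModel | None = None,
        missingness: MissingnessPlan | None = None,
    ) -> "StudyConfig":
        specs = default_task_specs(duration_scale, min_duration_s)
        return cls(
            n_participants=13,
            task_specs=tuple(specs),
            sensor_error=sensor_error if sensor_error is not None else SensorErrorModel.default(),
            missingness=(
                missingness if missingness is not None else default_missingness_plan(seed)
            ),
            sample_rate=100.0,
            seed=int(seed),
        )


def default_task_specs(
    duration_scale: float = 1.0, min_duration_s: float = 8.0
) -> list[TaskSpec]:
    """The 12-task battery with default durations and sway amplitudes.

    Standing eyes-open runs 120 s and eyes-closed 30 s per the study
    protocol; the remaining durations are desk-scale defaults. A
    ``duration_scale`` below 1 shrinks every task proportionally (floored
    at ``min_duration_s``) for fast test runs; the motion profiles are
    expressed relative to trial duration, so scaling preserves their shape.
    """
    base = [
        (1, "sit_to_stand", 10.0, (0.10, 0.01, 0.25)),
        (2, "quiet_sway", 120.0, (0.010, 0.008, 0.003)),
        (3, "sit_quiet", 30.0, (0.005, 0.004, 0.002)),
        (4, "eyes_closed_sway", 30.0, (0.014, 0.011, 0.004)),
        (5, "narrow_sway", 30.0, (0.020, 0.030, 0.005)),
        (6, "reach_forward", 10.0, (0.15, 0.01, 0.02)),
        (7, "pick_up", 10.0, (0.10, 0.01, 0.30)),
        (8, "look_over_shoulder", 15.0, (0.010, 0.030, 0.005)),
        (9, "turn_360", 10.0, (0.10, 0.10, 0.005)),
        (10, "alternate_step", 20.0, (0.020, 0.050, 0.020)),
        (11, "tandem_sway", 30.0, (0.018, 0.026, 0.005)),
        (12, "one_leg_sway", 30.0, (0.012, 0.018, 0.006)),
    ]
    return [
        TaskSpec(
            task_id=tid,
            motion_primitive=prim,
            duration_s=max(min_duration_s, duration_scale * dur),
            amplitude=amp,
            name=TASK_NAMES[tid],
        )
        for tid, prim, dur, amp in base
    ]


def default_missingness_plan(seed: int = 0, n_participants: int = 13) -> MissingnessPlan:
    """21 COM-missing + 8 tracker-missing disjoint trials over exactly 10 participants.

    The study being emulated reports these counts but not which trials were
    affected; the assignment is drawn pseudo-randomly from the seed, with
    each affected participant losing at least one trial.
    """
    n_affected = 10
    if n_participants < n_affected:
        raise ConfigurationError("default plan needs at least 10 participants")
    rng = np.random.default_rng([int(seed), 9001])
    affected = rng.choice(np.arange(1, n_participants + 1), size=n_affected, replace=False)
    cells: list[tuple[int, int]] = []
    seen = set()
    for p in affected:  # every affected participant loses >= 1 trial
        t = int(rng.integers(1, 13))
        cells.append((int(p), t))
        seen.add((int(p), t))
    while len(cells) < 29:
        p = int(rng.choice(affected))
        t = int(rng.integers(1, 13))
        if (p, t) not in seen:
            seen.add((p, t))
            cells.append((p, t))
    order = rng.permutation(29)
    shuffled = [cells[i] for i in order]
    return MissingnessPlan(
        com_missing_trials=frozenset(shuffled[:21]),
        tracker_missing_trials=frozenset(shuffled[21:]),
    )


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------
@dataclass
class TaskRecording:
    """One participant-task trial: both streams, event, ground truth."""

    participant_id: int
    task_id: int
    sample_rate: float
    clusters: dict[str, MarkerClusterSet] | None
    tracker_engine: TimeSeries3D | None
    event: AlignmentEvent
    truth_com: TimeSeries3D | None = None
    truth_tracker_lab: TimeSeries3D | None = None

    @property
    def com_missing(self) -> bool:
        return self.clusters is None

    @property
    def tracker_missing(self) -> bool:
        return self.tracker_engine is None

    def load(self) -> "TaskRecording":
        return self


@dataclass
class StudyDataset:
    """A full study: one recording per participant-task plus its provenance."""

    config: StudyConfig
    model: AnthropometricModel
    records: list

    @property
    def n_trials(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# motion primitives
# ---------------------------------------------------------------------------
def _minjerk(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Minimum-jerk unit step over [t0, t1] (0 before, 1 after)."""
    tau = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _sway_axis(t: np.ndarray, amp: float, spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    """Postural sway on one axis: sinusoid sum plus band-limited noise."""
    k = spec.n_sway_components
    lo, hi = spec.sway_band
    freqs = rng.uniform(lo, hi, size=k)
    phases = rng.uniform(0.0, 2 * np.pi, size=k)
    weights = rng.uniform(0.5, 1.0, size=k)
    weights /= weights.sum()
    det = np.zeros_like(t)
    for f, ph, w in zip(freqs, phases, weights):
        det += w * np.sin(2 * np.pi * f * t + ph)
    out = amp * (1.0 - spec.sway_noise_frac) * det
    if spec.sway_noise_frac > 0 and amp > 0:
        white = rng.standard_normal(t.size)
        nyq = 0.5 / (t[1] - t[0]) if t.size > 1 else 50.0
        b, a = butter(2, min(hi / nyq, 0.99))
        noise = filtfilt(b, a, white)
        sd = noise.std()
        if sd > 0:
            noise *= (spec.sway_noise_frac * amp / 2.0) / sd
        out = out + noise
    return out


def _sway(t: np.ndarray, spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack([_sway_axis(t, spec.amplitude[i], spec, rng) for i in range(3)])


def _bump(t: np.ndarray, dur: float, f0: float, f1: float, f2: float, f3: float) -> np.ndarray:
    """Smooth out-and-back profile: rises over [f0,f1]*dur, returns over [f2,f3]*dur."""
    return _minjerk(t, f0 * dur, f1 * dur) - _minjerk(t, f2 * dur, f3 * dur)


def _com_trajectory(
    t: np.ndarray, spec: TaskSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """Ground-truth COM path and, for turns, the body's base yaw angle."""
    prim = spec.motion_primitive
    dur = spec.duration_s
    ax, ay, az = spec.amplitude
    if prim in _SWAY_PRIMITIVES:
        base = _BASE_SIT if prim == "sit_quiet" else _BASE_STAND
        return base + _sway(t, spec, rng), None
    small = replace(spec, amplitude=(0.004, 0.004, 0.002), sway_noise_frac=0.2)
    residual = _sway(t, small, rng)
    if prim == "sit_to_stand":
        rise = _minjerk(t, 0.3 * dur, 0.7 * dur)
        path = _BASE_SIT + np.column_stack([ax * rise, ay * rise, az * rise])
        return path + residual, None
    if prim == "reach_forward":
        bump = _bump(t, dur, 0.20, 0.45, 0.55, 0.80)
        path = _BASE_STAND + np.column_stack([ax * bump, ay * bump, -az * bump])
        return path + residual, None
    if prim == "pick_up":
        bump = _bump(t, dur, 0.20, 0.40, 0.60, 0.80)
        path = _BASE_STAND + np.column_stack([ax * bump, ay * bump, -az * bump])
        return path + residual, None
    if prim == "look_over_shoulder":
        left = _bump(t, dur, 0.10, 0.25, 0.35, 0.50)
        right = _bump(t, dur, 0.55, 0.70, 0.80, 0.95)
        y = ay * (left - right)
        path = _BASE_STAND + np.column_stack([ax * (left + right) * 0.3, y, np.zeros_like(t)])
        return path + residual, None
    if prim == "turn_360":
        radius = ax
        theta = 2 * np.pi * _minjerk(t, 0.1 * dur, 0.9 * dur)
        path = _BASE_STAND + np.column_stack(
            [radius * (np.cos(theta) - 1.0), radius * np.sin(theta), np.zeros_like(t)]
        )
        path[:, 2] += _sway_axis(t, az, spec, rng)
        return path, theta
    if prim == "alternate_step":
        f_step = 0.25
        y = ay * np.sin(2 * np.pi * f_step * t)
        z = az * 0.5 * (1 - np.cos(4 * np.pi * f_step * t))
        x = _sway_axis(t, ax, spec, rng)
        return _BASE_STAND + np.column_stack([x, y, z]), None
    raise ConfigurationError(f"unknown motion primitive {prim!r}")  # pragma: no cover


def _segment_poses(
    t: np.ndarray,
    com: np.ndarray,
    base_yaw: np.ndarray | None,
    model: AnthropometricModel,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Construct per-segment (R, segment-COM point) streams whose
    mass-weighted COM equals ``com`` exactly."""
    n = t.size
    if base_yaw is not None:
        base_rot = Rotation.from_euler("z", base_yaw[:, None]).as_matrix()
    else:
        base_rot = np.broadcast_to(np.eye(3), (n, 3, 3))
    raw_points: dict[str, np.ndarray] = {}
    rotations: dict[str, np.ndarray] = {}
    for sid in model.segment_ids:
        offset = np.asarray(_SEGMENT_LAYOUT[sid])
        w_amp, r_amp = _SEGMENT_WIGGLE[sid]
        freqs = rng.uniform(0.2, 1.2, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        wig = w_amp * np.column_stack(
            [np.sin(2 * np.pi * freqs[i] * t + phases[i]) for i in range(3)]
        )
        raw_points[sid] = com + np.einsum("nij,j->ni", base_rot, offset) + wig
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        f_r, ph_r = rng.uniform(0.2, 1.0), rng.uniform(0, 2 * np.pi)
        angles = r_amp * np.sin(2 * np.pi * f_r * t + ph_r)
        wig_rot = Rotation.from_rotvec(angles[:, None] * axis[None, :]).as_matrix()
        rotations[sid] = np.einsum("nij,njk->nik", base_rot, wig_rot)
    # re-centre so the mass-weighted mean is exactly the requested COM
    weighted = np.zeros_like(com)
    for sid in model.segment_ids:
        weighted += model.mass_fraction(sid) * raw_points[sid]
    correction = weighted - com
    return {sid: (rotations[sid], raw_points[sid] - correction) for sid in model.segment_ids}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def generate_task_trial(
    spec: TaskSpec,
    error: SensorErrorModel,
    sample_rate: float = 100.0,
    seed=0,
    participant_id: int = 1,
    model: AnthropometricModel | None = None,
    mapping: FrameMapping = ENGINE_TO_LAB,
) -> TaskRecording:
    """Generate one trial: marker clusters, tracker stream, ground truth.

    All randomness is fixed by ``seed`` (an int or a seed sequence).
    """
    if sample_rate <= 0 or not np.isfinite(sample_rate):
        raise ValidationError("sample_rate must be positive and finite")
    model = model if model is not None else default_anthropometric_model()
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    n = max(int(round(spec.duration_s * sample_rate)), 2)
    t = np.arange(n) * dt

    com, base_yaw = _com_trajectory(t, spec, rng)
    poses = _segment_poses(t, com, base_yaw, model, rng)

    clusters: dict[str, MarkerClusterSet] = {}
    local = DEFAULT_MARKER_LOCAL
    for sid, (rot, seg_com) in poses.items():
        c = model.com_offset(sid)
        trans = seg_com - np.einsum("nij,j->ni", rot, c)
        observed = np.einsum("nij,mj->nmi", rot, local) + trans[:, None, :]
        clusters[sid] = MarkerClusterSet(sid, local.copy(), observed, t.copy())

    gain = np.asarray(error.sway_gain)
    offset = np.asarray(error.constant_offset)
    noise_sd = np.asarray(error.noise_sd)
    com_mean = com.mean(axis=0)
    tracker_lab = gain * (com - com_mean) + com_mean + offset
    if np.any(noise_sd > 0):
        tracker_lab = tracker_lab + rng.standard_normal((n, 3)) * noise_sd

    # tracker runs on its own clock, started a grid-commensurate lag later
    shift = dt * int(rng.integers(20, 101))
    tracker_times = t + shift
    event = AlignmentEvent(event_time_mocap=0.0, event_time_tracker=shift)
    if error.dropout_after_s is not None:
        keep = (tracker_times - tracker_times[0]) <= error.dropout_after_s + 1e-9
        if keep.sum() < 2:
            raise ConfigurationError("dropout_after_s leaves fewer than 2 tracker samples")
        tracker_lab = tracker_lab[keep]
        tracker_times = tracker_times[keep]

    truth_tracker = TimeSeries3D(tracker_times.copy(), tracker_lab.copy())
    engine_positions = mapping.inverse().apply(tracker_lab)
    tracker_engine = TimeSeries3D(tracker_times, engine_positions)

    return TaskRecording(
        participant_id=participant_id,
        task_id=spec.task_id,
        sample_rate=sample_rate,
        clusters=clusters,
        tracker_engine=tracker_engine,
        event=event,
        truth_com=TimeSeries3D(t.copy(), com.copy()),
        truth_tracker_lab=truth_tracker,
    )


def generate_study(
    config: StudyConfig,
    model: AnthropometricModel | None = None,
    mapping: FrameMapping = ENGINE_TO_LAB,
) -> StudyDataset:
    """Generate the full study: one recording per participant-task.

    Trials listed in the missingness plan have the corresponding stream
    removed but remain enumerated; ground truth is retained everywhere.
    Deterministic under a fixed config (each trial derives its own seed
    stream from ``(config.seed, participant, task)``).
    """
    model = model if model is not None else default_anthropometric_model()
    records = []
    for p in range(1, config.n_participants + 1):
        for spec in config.task_specs:
            rec = generate_task_trial(
                spec,
                config.sensor_error,
                sample_rate=config.sample_rate,
                seed=[int(config.seed), p, spec.task_id],
                participant_id=p,
                model=model,
                mapping=mapping,
            )
            key = (p, spec.task_id)
            if key in config.missingness.com_missing_trials:
                rec.clusters = None
            if key in config.missingness.tracker_missing_trials:
                rec.tracker_engine = None
            records.append(rec)
    return StudyDataset(config=config, model=model, records=records)
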