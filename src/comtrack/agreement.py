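"""Outcome measures: per-trial RMS error, displacement ranges, study summaries.

Per trial and per lab axis, the agreement between the optically derived
whole-body COM and the pelvis-tracker proxy is quantified as

    RMS_axis = sqrt( mean_t ( a_axis(t) - b_axis(t) )^2 )      [cm]

after the full preprocessing chain. For the five standing tasks, the
horizontal excursion of each method is summarised as the displacement
range, max - min of the time series per axis (X anteroposterior, Y
mediolateral), in cm. Trials missing either stream carry a status instead
of metrics; summaries report per-task n, mean and sample SD, a pooled
headline aggregate over all analysed trial-axis RMS values, and the
missing-trial accounting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import AnthropometricModel, default_anthropometric_model
from .errors import ValidationError
from .kinematics import compute_whole_body_com, estimate_segment_pose, pelvis_proxy_com
from .preprocess import (
    DEFAULT_SG_ORDER,
    DEFAULT_SG_WINDOW,
    ENGINE_TO_LAB,
    FrameMapping,
    align_time,
    remove_dc,
    smooth_savgol,
    translate_frame,
)
from .synthetic import STANDING_TASK_IDS, TASK_NAMES, TaskRecording
from .timeseries import TimeSeries3D

M_TO_CM = 100.0

STATUS_ANALYZED = "analyzed"
STATUS_COM_MISSING = "com_missing"
STATUS_TRACKER_MISSING = "tracker_missing"


@dataclass(frozen=True)
class AgreementRow:
    """Per-trial RMS error (cm per axis) or a missing-stream status."""

    participant_id: int
    task_id: int
    status: str
    rms: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.status == STATUS_ANALYZED) != (self.rms is not None):
            raise ValidationError("rms must be present iff status is 'analyzed'")
        if self.rms is not None and any(v < 0 for v in self.rms):
            raise ValidationError("rms must be non-negative")


@dataclass(frozen=True)
class DisplacementRow:
    """Per-trial, per-method displacement range (cm) on a standing task."""

    participant_id: int
    task_id: int
    method: str  # "com" | "tracker"
    range_x: float
    range_y: float

    def __post_init__(self) -> None:
        if self.method not in ("com", "tracker"):
            raise ValidationError("method must be 'com' or 'tracker'")
        if self.range_x < 0 or self.range_y < 0:
            raise ValidationError("ranges must be non-negative")


@dataclass(frozen=True)
class TaskSummary:
    """Per-task n, mean and sample SD of RMS per axis (cm)."""

    task_id: int
    task_name: str
    n: int
    mean: tuple[float, float, float] | None
    sd: tuple[float, float, float] | None


@dataclass(frozen=True)
class TrialAccounting:
    n_enumerated: int
    n_excluded: int
    n_com_missing: int
    n_tracker_missing: int
    n_participants_affected: int

    def __post_init__(self) -> None:
        if self.n_excluded != self.n_com_missing + self.n_tracker_missing:
            raise ValidationError("n_excluded must equal com + tracker missing")


@dataclass(frozen=True)
class StudySummary:
    task_summaries: list
    accounting: TrialAccounting
    grand_mean_cm: float
    grand_sd_cm: float


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def rms_error(a: TimeSeries3D, b: TimeSeries3D) -> np.ndarray:
    """Per-axis RMS difference between two aligned streams, in cm."""
    if a.n != b.n:
        raise ValidationError(f"stream lengths differ ({a.n} vs {b.n})")
    if a.n < 1:
        raise ValidationError("streams must be non-empty")
    diff = a.positions - b.positions
    return M_TO_CM * np.sqrt(np.mean(diff**2, axis=0))


def displacement_range(s: TimeSeries3D) -> tuple[float, float]:
    """(max - min) of the X and Y coordinate, in cm."""
    if s.n < 1:
        raise ValidationError("stream must be non-empty")
    span = s.positions.max(axis=0) - s.positions.min(axis=0)
    return float(M_TO_CM * span[0]), float(M_TO_CM * span[1])


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------
def analyze_trial(
    rec: TaskRecording,
    model: AnthropometricModel | None = None,
    mapping: FrameMapping = ENGINE_TO_LAB,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    dc_removal: bool = True,
) -> tuple[AgreementRow, list[DisplacementRow]]:
    """Run the full chain on one trial.

    kinematics (pose -> COM) -> registration/alignment/smoothing/DC ->
    RMS error, plus displacement ranges for the five standing tasks.
    Missing streams produce a status row, never an error. A trial whose
    COM stream has occluded frames is treated as COM-missing in full,
    mirroring how segment occlusion voids whole trials in practice.
    """
    model = model if model is not None else default_anthropometric_model()
    if rec.com_missing:
        return AgreementRow(rec.participant_id, rec.task_id, STATUS_COM_MISSING), []
    if rec.tracker_missing:
        return AgreementRow(rec.participant_id, rec.task_id, STATUS_TRACKER_MISSING), []

    poses = {sid: estimate_segment_pose(cl) for sid, cl in rec.clusters.items()}
    com = compute_whole_body_com(poses, model)
    if com.has_missing:
        return AgreementRow(rec.participant_id, rec.task_id, STATUS_COM_MISSING), []

    proxy = pelvis_proxy_com(translate_frame(rec.tracker_engine, mapping))
    a, b = align_time(com, proxy, rec.event, sample_rate=rec.sample_rate)
    a = smooth_savgol(a, sg_window, sg_order)
    b = smooth_savgol(b, sg_window, sg_order)
    if dc_removal:
        a = remove_dc(a)
        b = remove_dc(b)
    rms = rms_error(a, b)
    row = AgreementRow(rec.participant_id, rec.task_id, STATUS_ANALYZED, tuple(rms))
    disp: list[DisplacementRow] = []
    if rec.task_id in STANDING_TASK_IDS:
        for method, stream in (("com", a), ("tracker", b)):
            rx, ry = displacement_range(stream)
            disp.append(DisplacementRow(rec.participant_id, rec.task_id, method, rx, ry))
    return row, disp


def analyze_study(dataset, **kwargs) -> tuple[list, list]:
    """Analyse every trial of a study; returns (agreement rows, displacement rows).

    Accepts either an in-memory :class:`~comtrack.synthetic.StudyDataset`
    or a lazily loaded one; ``kwargs`` are forwarded to
    :func:`analyze_trial`.
    """
    kwargs.setdefault("model", getattr(dataset, "model", None))
    rows, disp = [], []
    for rec in dataset.records:
        row, d = analyze_trial(rec.load(), **kwargs)
        rows.append(row)
        disp.extend(d)
    return rows, disp


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def summarize_by_task(rows: list) -> StudySummary:
    """Aggregate per-trial rows into task summaries and trial accounting.

    Per-task moments use the sample (n-1) SD. The headline aggregate is
    the pooled mean +/- SD over all analysed trial-axis RMS values (each
    analysed trial contributes its X, Y and Z RMS).
    """
    by_task: dict[int, list[np.ndarray]] = {}
    task_ids = sorted({r.task_id for r in rows})
    n_com = sum(r.status == STATUS_COM_MISSING for r in rows)
    n_trk = sum(r.status == STATUS_TRACKER_MISSING for r in rows)
    affected = {r.participant_id for r in rows if r.status != STATUS_ANALYZED}
    for r in rows:
        if r.status == STATUS_ANALYZED:
            by_task.setdefault(r.task_id, []).append(np.asarray(r.rms))
    summaries = []
    pooled: list[float] = []
    for tid in task_ids:
        vals = by_task.get(tid, [])
        n = len(vals)
        if n == 0:
            summaries.append(TaskSummary(tid, TASK_NAMES.get(tid, str(tid)), 0, None, None))
            continue
        arr = np.vstack(vals)
        pooled.extend(arr.ravel().tolist())
        mean = tuple(arr.mean(axis=0))
        sd = tuple(arr.std(axis=0, ddof=1)) if n >= 2 else None
        summaries.append(TaskSummary(tid, TASK_NAMES.get(tid, str(tid)), n, mean, sd))
    accounting = TrialAccounting(
        n_enumerated=len(rows),
        n_excluded=n_com + n_trk,
        n_com_missing=n_com,
        n_tracker_missing=n_trk,
        n_participants_affected=len(affected),
    )
    pooled_arr = np.asarray(pooled)
    grand_mean = float(pooled_arr.mean()) if pooled_arr.size else float("nan")
    grand_sd = float(pooled_arr.std(ddof=1)) if pooled_arr.size >= 2 else float("nan")
    return StudySummary(summaries, accounting, grand_mean, grand_sd)
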