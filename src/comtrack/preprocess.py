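"""Frame registration, temporal alignment, smoothing and de-trending.

The pelvis tracker reports positions in the game engine's frame (left-handed,
y-up); the optical system reports in the lab frame (x forward, y left, z up).
Registration applies a signed axis permutation plus fixed translation. The
two streams are then aligned on a shared event (the game-start signal),
interpolated onto a common uniform grid, smoothed with a Savitzky–Golay
filter and mean-centred per axis.

Processing order here is: frame translation -> temporal alignment ->
smoothing -> DC removal. Aligning on the raw event timestamps is exact, and
the Savitzky–Golay filter is shift-invariant for grid-commensurate shifts,
so this order is equivalent to filtering first; it is also configurable at
the pipeline level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import AlignmentError, FilterError, ValidationError
from .timeseries import TimeSeries3D

#: default Savitzky-Golay window. The study protocol specifies a 40-point
#: window at 100 Hz; SG filters need an odd window, so the nearest odd
#: length (41 samples ~ 0.4 s) is used.
DEFAULT_SG_WINDOW = 41
DEFAULT_SG_ORDER = 3


@dataclass(frozen=True)
class FrameMapping:
    """Signed axis permutation + fixed translation between two frames.

    ``lab = matrix @ engine + translation``. The matrix must be a signed
    permutation (orthogonal, entries in {-1, 0, +1}, |det| = 1), so the
    mapping is an isometry and exactly invertible.
    """

    matrix: tuple = field(default=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
    translation: tuple = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        m = self.as_matrix()
        ok = (
            np.isin(m, (-1.0, 0.0, 1.0)).all()
            and (np.abs(m).sum(axis=0) == 1).all()
            and (np.abs(m).sum(axis=1) == 1).all()
        )
        if not ok:
            raise ValidationError("matrix must be a signed permutation of the axes")

    def as_matrix(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float).reshape(3, 3)

    def as_translation(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float).reshape(3)

    def inverse(self) -> "FrameMapping":
        m = self.as_matrix()
        mi = m.T  # signed permutations are orthogonal
        ti = -mi @ self.as_translation()
        return FrameMapping(tuple(map(tuple, mi)), tuple(ti))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.as_matrix().T + self.as_translation()


#: default engine->lab mapping for a left-handed y-up engine frame:
#: lab_X = engine_z, lab_Y = -engine_x, lab_Z = engine_y
ENGINE_TO_LAB = FrameMapping(((0, 0, 1), (-1, 0, 0), (0, 1, 0)))

IDENTITY_MAPPING = FrameMapping()


@dataclass(frozen=True)
class AlignmentEvent:
    """The shared event's time in each stream's own clock (seconds)."""

    event_time_mocap: float
    event_time_tracker: float


def translate_frame(tracker_raw: TimeSeries3D, mapping: FrameMapping) -> TimeSeries3D:
    """Re-express a stream through a signed-permutation frame mapping."""
    return TimeSeries3D(
        tracker_raw.timestamps.copy(),
        mapping.apply(tracker_raw.positions),
        None if tracker_raw.missing is None else tracker_raw.missing.copy(),
    )


def align_time(
    a: TimeSeries3D,
    b: TimeSeries3D,
    event: AlignmentEvent,
    sample_rate: float | None = None,
) -> tuple[TimeSeries3D, TimeSeries3D]:
    """Shift ``b`` so the event times coincide and resample both streams.

    Both streams are linearly interpolated onto a common uniform grid
    (default: ``a``'s rate, phase-locked to ``a``'s samples) restricted to
    their temporal overlap. Returns equal-length streams.
    """
    if a.has_missing or b.has_missing:
        raise AlignmentError("cannot align streams containing missing frames")
    if not (a.timestamps[0] - 1e-9 <= event.event_time_mocap <= a.timestamps[-1] + 1e-9):
        raise AlignmentError("mocap event time outside stream span")
    if not (b.timestamps[0] - 1e-9 <= event.event_time_tracker <= b.timestamps[-1] + 1e-9):
        raise AlignmentError("tracker event time outside stream span")
    shift = event.event_time_mocap - event.event_time_tracker
    tb = b.timestamps + shift
    rate = float(sample_rate) if sample_rate is not None else a.sample_rate
    dt = 1.0 / rate
    start = max(a.timestamps[0], tb[0])
    stop = min(a.timestamps[-1], tb[-1])
    # phase-lock the common grid to a's samples
    k0 = int(np.ceil((start - a.timestamps[0]) / dt - 1e-9))
    k1 = int(np.floor((stop - a.timestamps[0]) / dt + 1e-9))
    if k1 - k0 + 1 < 2:
        raise AlignmentError("streams overlap by fewer than 2 samples")
    grid = a.timestamps[0] + np.arange(k0, k1 + 1) * dt
    pos_a = np.column_stack([np.interp(grid, a.timestamps, a.positions[:, i]) for i in range(3)])
    pos_b = np.column_stack([np.interp(grid, tb, b.positions[:, i]) for i in range(3)])
    return TimeSeries3D(grid, pos_a), TimeSeries3D(grid.copy(), pos_b)


def smooth_savgol(
    s: TimeSeries3D,
    window_samples: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_ORDER,
) -> TimeSeries3D:
    """Savitzky–Golay smooth each axis; edges handled by mirror padding.

    Even windows are bumped to the next odd length (SG filters require a
    symmetric window).
    """
    if s.has_missing:
        raise FilterError("cannot filter a stream containing missing frames")
    window = int(window_samples)
    if window % 2 == 0:
        window += 1
    if poly_order >= window:
        raise FilterError(f"poly_order {poly_order} must be < window {window}")
    if s.n < window:
        raise FilterError(f"series of length {s.n} shorter than window {window}")
    smoothed = savgol_filter(s.positions, window, int(poly_order), axis=0, mode="mirror")
    return TimeSeries3D(s.timestamps.copy(), smoothed)


def remove_dc(s: TimeSeries3D) -> TimeSeries3D:
    """Subtract the per-axis mean (DC offset) from the stream."""
    if s.has_missing:
        raise ValidationError("cannot remove DC from a stream with missing frames")
    return TimeSeries3D(s.timestamps.copy(), s.positions - s.positions.mean(axis=0))


def preprocess_pair(
    com_lab: TimeSeries3D,
    tracker_engine: TimeSeries3D,
    event: AlignmentEvent,
    mapping: FrameMapping = ENGINE_TO_LAB,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    dc_removal: bool = True,
    sample_rate: float | None = None,
) -> tuple[TimeSeries3D, TimeSeries3D]:
    """Full chain: frame translation -> alignment -> smoothing -> DC removal."""
    tracker_lab = translate_frame(tracker_engine, mapping)
    a, b = align_time(com_lab, tracker_lab, event, sample_rate=sample_rate)
    a = smooth_savgol(a, sg_window, sg_order)
    b = smooth_savgol(b, sg_window, sg_order)
    if dc_removal:
        a = remove_dc(a)
        b = remove_dc(b)
    return a, b
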