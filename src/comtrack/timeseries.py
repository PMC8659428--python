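"""Uniformly sampled 3-D position trajectories.

All trajectories in the package live in the laboratory frame unless stated
otherwise: X points forward (anteroposterior), Y points to the subject's
left (mediolateral) and Z points up. Positions are in metres; reporting
code converts to centimetres only at the very end.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: tolerated deviation of individual time steps from the nominal step (s)
TIME_JITTER_TOL = 1e-6


@dataclass
class TimeSeries3D:
    """A uniformly sampled 3-D position trajectory.

    Parameters
    ----------
    timestamps:
        Sample times in seconds, strictly increasing with a constant step
        (within :data:`TIME_JITTER_TOL`).
    positions:
        ``(n, 3)`` array of positions in metres.
    missing:
        Optional boolean mask of frames whose position is unavailable
        (e.g. marker occlusion upstream). Masked frames may hold NaN;
        unmasked frames must be finite.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    missing: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.timestamps = np.atleast_1d(np.asarray(self.timestamps, dtype=float))
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape != (self.timestamps.size, 3):
            raise ValidationError(
                f"positions must have shape ({self.timestamps.size}, 3), "
                f"got {self.positions.shape}"
            )
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool).ravel()
            if self.missing.size != self.timestamps.size:
                raise ValidationError("missing mask length does not match timestamps")
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        t = self.timestamps
        if t.size < 1:
            raise ValidationError("time series must contain at least one sample")
        if not np.all(np.isfinite(t)):
            raise ValidationError("timestamps must be finite")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            dt = np.median(steps)
            if np.any(np.abs(steps - dt) > TIME_JITTER_TOL):
                raise ValidationError(
                    "timestamps are not uniform within tolerance "
                    f"({TIME_JITTER_TOL} s)"
                )
        valid = np.ones(t.size, dtype=bool) if self.missing is None else ~self.missing
        if not np.all(np.isfinite(self.positions[valid])):
            raise ValidationError("positions contain non-finite values in observed frames")

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def dt(self) -> float:
        if self.n < 2:
            raise ValidationError("sample step undefined for a single-sample series")
        return float(np.median(np.diff(self.timestamps)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def has_missing(self) -> bool:
        return self.missing is not None and bool(self.missing.any())

    def shifted(self, offset_s: float) -> "TimeSeries3D":
        """Return a copy with all timestamps shifted by ``offset_s`` seconds."""
        return TimeSeries3D(
            self.timestamps + float(offset_s),
            self.positions.copy(),
            None if self.missing is None else self.missing.copy(),
        )

    def copy(self) -> "TimeSeries3D":
        return TimeSeries3D(
            self.timestamps.copy(),
            self.positions.copy(),
            None if self.missing is None else self.missing.copy(),
        )
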