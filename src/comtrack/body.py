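"""Anthropometric segment parameters for whole-body centre-of-mass composition.

The whole-body COM is a mass-fraction weighted sum of per-segment COM
positions. The default table merges the body into eleven segments (head,
thorax+abdomen, pelvis, and left/right arm, thigh, shank, foot) with
mass fractions adapted from standard adjusted segment-inertia tables
(de Leva-style). The arm entries merge upper arm, forearm and hand into a
single rigid segment per side — sufficient for COM composition, which only
needs each segment's mass fraction and COM point.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MASS_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class SegmentParams:
    """Mass fraction and COM location (metres, segment frame) of one segment."""

    mass_fraction: float
    com_offset: tuple[float, float, float]


@dataclass
class AnthropometricModel:
    """Per-segment mass fractions and segment-frame COM offsets.

    Invariants: all mass fractions strictly positive and summing to one
    (within :data:`MASS_FRACTION_TOL`).
    """

    segments: dict[str, SegmentParams]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("anthropometric model has no segments")
        fracs = np.array([s.mass_fraction for s in self.segments.values()])
        if np.any(fracs <= 0):
            raise ConfigurationError("mass fractions must be strictly positive")
        if abs(fracs.sum() - 1.0) > MASS_FRACTION_TOL:
            raise ConfigurationError(
                f"mass fractions must sum to 1 (got {fracs.sum():.12f})"
            )

    @property
    def segment_ids(self) -> list[str]:
        return list(self.segments)

    def mass_fraction(self, segment_id: str) -> float:
        return self.segments[segment_id].mass_fraction

    def com_offset(self, segment_id: str) -> np.ndarray:
        return np.asarray(self.segments[segment_id].com_offset, dtype=float)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "AnthropometricModel":
        """Read a table with columns segment_id, mass_fraction, com_offset_{x,y,z}."""
        df = pd.read_csv(path, comment="#")
        required = {"segment_id", "mass_fraction", "com_offset_x", "com_offset_y", "com_offset_z"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"anthropometric table missing columns: {sorted(missing)}")
        segments = {
            str(r.segment_id): SegmentParams(
                float(r.mass_fraction),
                (float(r.com_offset_x), float(r.com_offset_y), float(r.com_offset_z)),
            )
            for r in df.itertuples()
        }
        return cls(segments)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "segment_id": sid,
                "mass_fraction": p.mass_fraction,
                "com_offset_x": p.com_offset[0],
                "com_offset_y": p.com_offset[1],
                "com_offset_z": p.com_offset[2],
            }
            for sid, p in self.segments.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_anthropometric_model() -> AnthropometricModel:
    """Eleven-segment default model (fractions sum to exactly 1.0).

    COM offsets are expressed in each segment's cluster frame, i.e. relative
    to the rigid marker plate's origin, pointing from the plate towards the
    segment's interior.
    """
    seg = {
        "pelvis": SegmentParams(0.1117, (-0.05, 0.0, -0.02)),
        "thorax": SegmentParams(0.3229, (-0.06, 0.0, -0.10)),
        "head": SegmentParams(0.0694, (-0.02, 0.0, -0.04)),
        "arm_l": SegmentParams(0.0494, (0.0, -0.03, -0.12)),
        "arm_r": SegmentParams(0.0494, (0.0, 0.03, -0.12)),
        "thigh_l": SegmentParams(0.1416, (-0.03, -0.01, -0.10)),
        "thigh_r": SegmentParams(0.1416, (-0.03, 0.01, -0.10)),
        "shank_l": SegmentParams(0.0433, (-0.02, -0.01, -0.08)),
        "shank_r": SegmentParams(0.0433, (-0.02, 0.01, -0.08)),
        "foot_l": SegmentParams(0.0137, (0.03, 0.0, -0.02)),
        "foot_r": SegmentParams(0.0137, (0.03, 0.0, -0.02)),
    }
    return AnthropometricModel(seg)


#: default rigid plate geometry shared by all synthetic marker clusters:
#: four non-coplanar markers (metres, segment frame)
DEFAULT_MARKER_LOCAL = np.array(
    [
        [0.05, 0.05, 0.0],
        [-0.05, 0.05, 0.0],
        [0.05, -0.05, 0.0],
        [-0.03, 0.0, 0.04],
    ]
)
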