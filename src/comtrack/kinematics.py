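"""Rigid-body pose recovery from marker clusters and whole-body COM composition.

Each body segment carries a rigid plate with at least three reflective
markers whose positions are known in the segment frame. Per frame, the
segment's pose ``(R, t)`` is the least-squares solution of the orthogonal
Procrustes problem

    minimise  sum_i || R @ local_i + t - observed_i ||^2,   det(R) = +1,

solved in closed form via the SVD of the marker cross-covariance (Kabsch).
The whole-body centre of mass is then the mass-fraction weighted sum of
per-segment COM points,

    COM(t) = sum_s  m_s * ( R_s(t) @ c_s + t_s(t) ),

where ``m_s`` are anthropometric mass fractions summing to one and ``c_s``
is the segment-frame COM offset. Frames where a segment cannot be solved
(fewer than three observed markers) are flagged missing and propagate to
the COM stream — the occlusion mechanism that makes whole trials unusable
in practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .body import AnthropometricModel
from .errors import ConfigurationError, DegenerateGeometryError, ValidationError
from .timeseries import TimeSeries3D

_COLLINEAR_TOL = 1e-10


@dataclass
class MarkerClusterSet:
    """Observed marker trajectories for one segment's rigid plate.

    ``local_coords`` is the ``(m, 3)`` marker geometry in the segment frame;
    ``observed`` is the ``(n, m, 3)`` lab-frame trajectory. Markers may be
    unobserved in individual frames: either flag them in ``observed_mask``
    or leave NaN in ``observed``.
    """

    segment_id: str
    local_coords: np.ndarray
    observed: np.ndarray
    timestamps: np.ndarray
    observed_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.local_coords = np.asarray(self.local_coords, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float).ravel()
        m = self.local_coords.shape[0]
        if self.local_coords.ndim != 2 or self.local_coords.shape[1] != 3 or m < 3:
            raise ValidationError("local_coords must be (m>=3, 3)")
        if self.observed.shape != (self.timestamps.size, m, 3):
            raise ValidationError(
                f"observed must have shape ({self.timestamps.size}, {m}, 3)"
            )
        if _is_collinear(self.local_coords):
            raise DegenerateGeometryError(
                f"segment {self.segment_id!r}: local marker geometry is collinear"
            )
        finite = np.isfinite(self.observed).all(axis=2)
        if self.observed_mask is None:
            self.observed_mask = finite
        else:
            self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
            if self.observed_mask.shape != (self.timestamps.size, m):
                raise ValidationError("observed_mask shape mismatch")
            self.observed_mask &= finite

    @property
    def n_frames(self) -> int:
        return self.timestamps.size


@dataclass
class SegmentPose:
    """Per-frame rigid pose of one segment: rotations (n,3,3), translations (n,3).

    ``residual`` is the per-frame RMS marker fit error (m). Missing frames
    hold NaN in all fields and True in ``missing``.
    """

    segment_id: str
    timestamps: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray
    residuals: np.ndarray
    missing: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.timestamps.size


def _is_collinear(points: np.ndarray) -> bool:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return bool(s[1] <= _COLLINEAR_TOL * max(s[0], 1.0))


def _kabsch_batch(local: np.ndarray, observed: np.ndarray):
    """Solve the Procrustes problem for every frame at once.

    local: (m, 3) ; observed: (n, m, 3) with all markers observed.
    Returns (R (n,3,3), t (n,3), rms residual (n,)).
    """
    lbar = local.mean(axis=0)
    l0 = local - lbar
    ybar = observed.mean(axis=1)
    y0 = observed - ybar[:, None, :]
    # cross-covariance H_f = sum_m l0_m (y0_{f,m})^T
    h = np.einsum("mi,nmj->nij", l0, y0)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("nij,nkj->nik", np.swapaxes(vt, 1, 2), u))
    d = np.ones_like(s)
    d[:, 2] = np.sign(det)
    # R = V diag(d) U^T
    r = np.einsum("nji,nj,nkj->nik", vt, d, u)
    t = ybar - np.einsum("nij,j->ni", r, lbar)
    fitted = np.einsum("nij,mj->nmi", r, local) + t[:, None, :]
    res = np.sqrt(np.mean(np.sum((fitted - observed) ** 2, axis=2), axis=1))
    return r, t, res


def estimate_segment_pose(cluster: MarkerClusterSet) -> SegmentPose:
    """Recover the per-frame rigid pose of a segment from its marker cluster.

    Frames with fewer than three observed markers are flagged missing rather
    than raised; frames whose *observed* markers are collinear (pose not
    identifiable) raise :class:`DegenerateGeometryError`.
    """
    n = cluster.n_frames
    mask = cluster.observed_mask
    rot = np.full((n, 3, 3), np.nan)
    trans = np.full((n, 3), np.nan)
    res = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)

    full = mask.all(axis=1)
    solvable_partial = ~full & (mask.sum(axis=1) >= 3)
    missing[mask.sum(axis=1) < 3] = True

    degenerate_frames: list[int] = []
    if full.any():
        obs = cluster.observed[full]
        # identifiability: observed markers of a rigid plate are collinear
        # only if the plate geometry itself is degenerate in those frames
        centred = obs - obs.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(centred, compute_uv=False)
        bad = sv[:, 1] <= _COLLINEAR_TOL * np.maximum(sv[:, 0], 1.0)
        if bad.any():
            degenerate_frames.extend(np.flatnonzero(full)[bad].tolist())
        r, t, rr = _kabsch_batch(cluster.local_coords, obs)
        rot[full], trans[full], res[full] = r, t, rr
    for f in np.flatnonzero(solvable_partial):
        sel = mask[f]
        local = cluster.local_coords[sel]
        if _is_collinear(local) or _is_collinear(cluster.observed[f, sel]):
            degenerate_frames.append(int(f))
            continue
        r, t, rr = _kabsch_batch(local, cluster.observed[None, f, sel])
        rot[f], trans[f], res[f] = r[0], t[0], rr[0]
    if degenerate_frames:
        raise DegenerateGeometryError(
            f"segment {cluster.segment_id!r}: observed markers collinear in "
            f"frames {sorted(degenerate_frames)[:10]}"
        )
    return SegmentPose(cluster.segment_id, cluster.timestamps, rot, trans, res, missing)


def compute_whole_body_com(
    poses: Mapping[str, SegmentPose], model: AnthropometricModel
) -> TimeSeries3D:
    """Compose the whole-body COM trajectory from segment poses.

    Every model segment must have a pose stream on a common time base.
    Frames where any required segment is missing are flagged missing in
    the returned stream.
    """
    missing_segments = [s for s in model.segment_ids if s not in poses]
    if missing_segments:
        raise ConfigurationError(
            f"no pose stream for model segments: {missing_segments}"
        )
    ref = poses[model.segment_ids[0]]
    n = ref.n_frames
    com = np.zeros((n, 3))
    miss = np.zeros(n, dtype=bool)
    for sid in model.segment_ids:
        pose = poses[sid]
        if pose.n_frames != n or not np.allclose(pose.timestamps, ref.timestamps, atol=1e-9):
            raise ConfigurationError(f"segment {sid!r} is not on the common time base")
        c = model.com_offset(sid)
        seg_com = np.einsum("nij,j->ni", pose.rotations, c) + pose.translations
        com += model.mass_fraction(sid) * seg_com
        miss |= pose.missing
    com[miss] = np.nan
    return TimeSeries3D(ref.timestamps.copy(), com, missing=miss if miss.any() else None)


def pelvis_proxy_com(tracker: TimeSeries3D) -> TimeSeries3D:
    """The pelvis-tracker approximation of whole-body COM.

    An explicit identity stage: the tracker position (already in the lab
    frame) *is* the proxy COM. Exists as a named step so a different proxy
    definition can be swapped in; performs stream-level validation only.
    """
    if tracker.has_missing:
        raise ValidationError("tracker stream contains missing frames")
    tracker.validate()  # finiteness + uniform sampling contract
    return tracker.copy()
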