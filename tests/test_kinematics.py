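"""Pose estimation and whole-body COM composition."""
import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

import comtrack as ct
from comtrack.kinematics import SegmentPose

LOCAL4 = np.array(
    [[0.05, 0.05, 0.0], [-0.05, 0.05, 0.0], [0.05, -0.05, 0.0], [-0.03, 0.0, 0.04]]
)


def _cluster(observed, local=LOCAL4, **kw):
    observed = np.asarray(observed, float)
    t = np.arange(observed.shape[0]) * 0.01
    return ct.MarkerClusterSet("seg", local, observed, t, **kw)


def _pose_from(r, t, local=LOCAL4, noise=0.0, rng=None):
    obs = local @ np.asarray(r).T + np.asarray(t)
    if noise:
        obs = obs + rng.normal(scale=noise, size=obs.shape)
    return ct.estimate_segment_pose(_cluster(obs[None], local=local))


class TestEstimateSegmentPose:
    def test_identity_case(self):
        pose = ct.estimate_segment_pose(_cluster(LOCAL4[None]))
        np.testing.assert_allclose(pose.rotations[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translations[0], 0.0, atol=1e-12)
        assert pose.residuals[0] < 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_construct_and_recover(self, seed):
        """Noise-free rigid transforms are recovered exactly."""
        rng = np.random.default_rng(seed)
        n_markers = int(rng.integers(3, 9))
        local = rng.normal(scale=0.08, size=(n_markers, 3))
        r0 = Rotation.random(rng=rng).as_matrix()
        t0 = rng.normal(scale=0.5, size=3)
        pose = _pose_from(r0, t0, local=local)
        assert np.linalg.det(pose.rotations[0]) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(pose.rotations[0], r0, atol=1e-9)
        np.testing.assert_allclose(pose.translations[0], t0, atol=1e-9)
        assert pose.residuals[0] < 1e-9

    def test_noisy_recovery_residual_and_marker_count(self, rng):
        """Residual stays near the noise floor and rotation error shrinks
        as the marker count grows from 3 to 8."""
        sigma = 0.003
        errs = {}
        for m in (3, 8):
            rot_errs = []
            for _ in range(40):
                local = rng.normal(scale=0.08, size=(m, 3))
                r0 = Rotation.random(rng=rng).as_matrix()
                t0 = rng.normal(scale=0.3, size=3)
                pose = _pose_from(r0, t0, local=local, noise=sigma, rng=rng)
                assert pose.residuals[0] <= 3 * sigma
                rot_errs.append(np.linalg.norm(pose.rotations[0] - r0))
            errs[m] = np.mean(rot_errs)
        assert errs[8] < errs[3]

    def test_brute_force_oracle_agreement(self, rng):
        """SVD solution matches dense rotation-space search on noisy
        4-marker instances: objectives agree to 1e-6."""
        from conftest import brute_force_pose, procrustes_objective

        for _ in range(20):
            local = rng.normal(scale=0.08, size=(4, 3))
            r0 = Rotation.random(rng=rng).as_matrix()
            t0 = rng.normal(scale=0.4, size=3)
            obs = local @ r0.T + t0 + rng.normal(scale=0.005, size=(4, 3))
            pose = ct.estimate_segment_pose(_cluster(obs[None], local=local))
            l0 = local - local.mean(axis=0)
            y0 = obs - obs.mean(axis=0)
            obj_svd = float(procrustes_objective(pose.rotations, l0, y0)[0])
            _, _, obj_bf = brute_force_pose(local, obs)
            assert obj_svd <= obj_bf + 1e-9  # SVD is the true minimiser
            assert abs(obj_svd - obj_bf) <= 1e-6

    def test_few_markers_frames_flagged_missing(self):
        obs = np.repeat(LOCAL4[None], 3, axis=0).copy()
        obs[1, :2] = np.nan  # only 2 markers observed in frame 1
        pose = ct.estimate_segment_pose(_cluster(obs))
        assert pose.missing.tolist() == [False, True, False]
        assert np.isnan(pose.rotations[1]).all()

    def test_partial_frame_with_three_markers_solved(self):
        obs = np.repeat(LOCAL4[None], 2, axis=0).copy()
        obs[1, 3] = np.nan
        pose = ct.estimate_segment_pose(_cluster(obs))
        assert not pose.missing.any()
        np.testing.assert_allclose(pose.rotations[1], np.eye(3), atol=1e-9)

    def test_collinear_local_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        with pytest.raises(ct.DegenerateGeometryError):
            _cluster(line[None], local=line)

    def test_collinear_observed_markers_rejected(self):
        obs = np.array([[[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0]]])
        with pytest.raises(ct.DegenerateGeometryError):
            ct.estimate_segment_pose(_cluster(obs))


def _simple_pose(points):
    """A SegmentPose with identity rotations through the given points."""
    points = np.asarray(points, float)
    n = points.shape[0]
    return SegmentPose(
        "s",
        np.arange(n) * 0.01,
        np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        points,
        np.zeros(n),
        np.zeros(n, bool),
    )


def _two_segment_model(f1=0.5, f2=0.5):
    return ct.AnthropometricModel(
        {
            "a": ct.SegmentParams(f1, (0.0, 0.0, 0.0)),
            "b": ct.SegmentParams(f2, (0.0, 0.0, 0.0)),
        }
    )


class TestWholeBodyCom:
    def test_midpoint_of_equal_masses(self):
        poses = {"a": _simple_pose([[0, 0, 0]]), "b": _simple_pose([[1, 0, 0]])}
        com = ct.compute_whole_body_com(poses, _two_segment_model())
        np.testing.assert_allclose(com.positions[0], [0.5, 0, 0], atol=1e-12)

    def test_coincident_segments_any_weights(self):
        p = np.array([0.3, -0.2, 1.1])
        poses = {"a": _simple_pose([p]), "b": _simple_pose([p])}
        com = ct.compute_whole_body_com(poses, _two_segment_model(0.37, 0.63))
        np.testing.assert_allclose(com.positions[0], p, atol=1e-12)

    def test_generator_round_trip(self):
        """COM recomposed from generated marker clusters equals the stored
        ground truth within 1e-9 m per frame."""
        spec = ct.default_task_specs(duration_scale=0.1, min_duration_s=5.0)[8]  # turn
        rec = ct.generate_task_trial(spec, ct.SensorErrorModel.default(), seed=21)
        poses = {s: ct.estimate_segment_pose(c) for s, c in rec.clusters.items()}
        com = ct.compute_whole_body_com(poses, ct.default_anthropometric_model())
        assert np.abs(com.positions - rec.truth_com.positions).max() < 1e-9

    def test_affine_equivariance(self, rng):
        """Rigidly transforming all poses transforms the COM identically."""
        model = ct.default_anthropometric_model()
        spec = ct.default_task_specs(duration_scale=0.05, min_duration_s=5.0)[1]
        rec = ct.generate_task_trial(spec, ct.SensorErrorModel.identity(), seed=3)
        poses = {s: ct.estimate_segment_pose(c) for s, c in rec.clusters.items()}
        com = ct.compute_whole_body_com(poses, model)
        r0 = Rotation.random(rng=rng).as_matrix()
        t0 = rng.normal(scale=1.0, size=3)
        moved = {
            s: SegmentPose(
                s,
                p.timestamps,
                np.einsum("ij,njk->nik", r0, p.rotations),
                p.translations @ r0.T + t0,
                p.residuals,
                p.missing,
            )
            for s, p in poses.items()
        }
        com2 = ct.compute_whole_body_com(moved, model)
        expected = com.positions @ r0.T + t0
        np.testing.assert_allclose(com2.positions, expected, atol=1e-9)

    def test_com_inside_convex_hull_of_segment_points(self):
        model = ct.default_anthropometric_model()
        spec = ct.default_task_specs(duration_scale=0.05, min_duration_s=5.0)[4]
        rec = ct.generate_task_trial(spec, ct.SensorErrorModel.identity(), seed=9)
        poses = {s: ct.estimate_segment_pose(c) for s, c in rec.clusters.items()}
        com = ct.compute_whole_body_com(poses, model)
        for f in range(0, rec.truth_com.n, 97):
            pts = np.array(
                [
                    poses[s].rotations[f] @ model.com_offset(s) + poses[s].translations[f]
                    for s in model.segment_ids
                ]
            )
            assert Delaunay(pts).find_simplex(com.positions[f]) >= 0

    def test_missing_segment_frames_propagate(self):
        poses = {"a": _simple_pose([[0, 0, 0], [0, 0, 0]]), "b": _simple_pose([[1, 0, 0], [1, 0, 0]])}
        poses["b"].missing[1] = True
        com = ct.compute_whole_body_com(poses, _two_segment_model())
        assert com.missing.tolist() == [False, True]

    def test_model_pose_mismatch_raises(self):
        with pytest.raises(ct.ConfigurationError):
            ct.compute_whole_body_com({"a": _simple_pose([[0, 0, 0]])}, _two_segment_model())


class TestPelvisProxy:
    def test_identity_pass_through(self):
        s = ct.TimeSeries3D(np.arange(10) * 0.01, np.random.default_rng(0).normal(size=(10, 3)))
        out = ct.pelvis_proxy_com(s)
        np.testing.assert_array_equal(out.positions, s.positions)
        assert out is not s

    def test_nan_frame_rejected(self):
        pos = np.zeros((10, 3))
        pos[3, 1] = np.nan
        with pytest.raises(ct.ValidationError):
            ct.pelvis_proxy_com(ct.TimeSeries3D(np.arange(10) * 0.01, pos))

    def test_jittered_timestamps_rejected(self):
        t = np.arange(10) * 0.01
        t[5] += 0.004
        with pytest.raises(ct.ValidationError):
            ct.TimeSeries3D(t, np.zeros((10, 3)))
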