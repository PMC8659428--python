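"""RMS error, displacement ranges, trial analysis and study summaries."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import comtrack as ct
from comtrack.agreement import (
    STATUS_ANALYZED,
    STATUS_COM_MISSING,
    STATUS_TRACKER_MISSING,
    AgreementRow,
)


def _series(positions, rate=100.0):
    positions = np.asarray(positions, float)
    return ct.TimeSeries3D(np.arange(positions.shape[0]) / rate, positions)


class TestRmsError:
    def test_identical_streams_zero(self):
        s = _series(np.random.default_rng(0).normal(size=(64, 3)))
        np.testing.assert_allclose(ct.rms_error(s, s.copy()), 0.0, atol=1e-12)

    def test_constant_offset(self):
        s = _series(np.zeros((50, 3)))
        b = _series(np.zeros((50, 3)) + np.array([0.02, 0.0, 0.0]))
        np.testing.assert_allclose(ct.rms_error(s, b), [2.0, 0.0, 0.0], atol=1e-12)

    def test_sinusoid_closed_form_vs_direct_summation(self):
        """RMS of A sin over integer periods = 100*A/sqrt(2) cm, and the
        vectorised result equals an explicit per-sample summation."""
        amp, f = 0.03, 0.5
        t = np.arange(1000) / 100.0  # 5 whole periods
        pos = np.zeros((1000, 3))
        pos[:, 1] = amp * np.sin(2 * np.pi * f * t)
        a, b = _series(np.zeros((1000, 3))), _series(pos)
        rms = ct.rms_error(a, b)
        assert rms[1] == pytest.approx(100 * amp / np.sqrt(2), rel=1e-9)
        acc = 0.0
        for k in range(1000):  # independent direct summation
            acc += pos[k, 1] ** 2
        assert rms[1] == pytest.approx(100 * np.sqrt(acc / 1000), rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ct.ValidationError):
            ct.rms_error(_series(np.zeros((5, 3))), _series(np.zeros((6, 3))))

    @given(seed=st.integers(0, 2**16))
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = _series(rng.normal(size=(32, 3)))
        b = _series(rng.normal(size=(32, 3)))
        np.testing.assert_allclose(ct.rms_error(a, b), ct.rms_error(b, a), atol=1e-12)
        shift = rng.normal(size=3)
        a2 = _series(a.positions + shift)
        b2 = _series(b.positions + shift)
        np.testing.assert_allclose(ct.rms_error(a2, b2), ct.rms_error(a, b), atol=1e-9)


class TestDisplacementRange:
    def test_constant_series(self):
        assert ct.displacement_range(_series(np.full((10, 3), 2.0))) == (0.0, 0.0)

    def test_sinusoid_diameter(self):
        amp = 0.05
        t = np.arange(2000) / 100.0
        pos = np.zeros((2000, 3))
        pos[:, 0] = amp * np.sin(2 * np.pi * 0.35 * t)
        rx, ry = ct.displacement_range(_series(pos))
        assert rx == pytest.approx(2 * amp * 100, rel=5e-3)
        assert ry == 0.0

    def test_monotone_ramp_endpoints(self):
        pos = np.zeros((101, 3))
        pos[:, 1] = np.linspace(0.0, 0.2, 101)
        assert ct.displacement_range(_series(pos))[1] == pytest.approx(20.0, abs=1e-12)

    def test_invariant_under_dc_removal_and_time_shift(self):
        rng = np.random.default_rng(5)
        s = _series(np.cumsum(rng.normal(size=(200, 3)), axis=0) * 0.01)
        base = ct.displacement_range(s)
        assert ct.displacement_range(ct.remove_dc(s)) == pytest.approx(base, abs=1e-9)
        assert ct.displacement_range(s.shifted(3.7)) == base


class TestAnalyzeTrial:
    def test_missing_streams_become_statuses(self):
        spec = ct.default_task_specs(0.02, 3.0)[1]
        rec = ct.generate_task_trial(spec, ct.SensorErrorModel.identity(), seed=1)
        rec.clusters = None
        row, disp = ct.analyze_trial(rec)
        assert row.status == STATUS_COM_MISSING and row.rms is None and disp == []
        rec2 = ct.generate_task_trial(spec, ct.SensorErrorModel.identity(), seed=1)
        rec2.tracker_engine = None
        row2, _ = ct.analyze_trial(rec2)
        assert row2.status == STATUS_TRACKER_MISSING

    def test_identity_error_model_rms_zero(self):
        spec = ct.default_task_specs(0.05, 5.0)[1]
        rec = ct.generate_task_trial(spec, ct.SensorErrorModel.identity(), seed=2)
        row, disp = ct.analyze_trial(rec)
        assert row.status == STATUS_ANALYZED
        assert max(row.rms) < 1e-9
        assert len(disp) == 2  # standing task: one row per method

    def test_gain_on_sinusoid_closed_form(self):
        """Pure sinusoidal sway with tracker gain g: RMS_X after DC removal
        is 100*|g-1|*A/sqrt(2) cm within 2%."""
        amp, g = 0.03, 1.5
        spec = ct.TaskSpec(
            2, "quiet_sway", 30.0, (amp, 0.0, 0.0),
            sway_band=(0.4, 0.4), n_sway_components=1, sway_noise_frac=0.0,
        )
        err = ct.SensorErrorModel(sway_gain=(g, 1.0, 1.0))
        rec = ct.generate_task_trial(spec, err, seed=3)
        row, _ = ct.analyze_trial(rec)
        assert row.rms[0] == pytest.approx(100 * abs(g - 1) * amp / np.sqrt(2), rel=0.02)
        assert row.rms[1] < 1e-6 and row.rms[2] < 1e-6

    def test_sway_gain_ordering_recovered(self):
        """Per-task mean RMS orders exactly as |g-1| * sway scale at zero
        noise (Spearman rho = 1)."""
        gains = [1.05, 1.4, 0.8, 1.2, 1.9, 0.95]
        amps = [0.010, 0.012, 0.020, 0.008, 0.015, 0.030]
        measured, predicted = [], []
        for i, (g, amp) in enumerate(zip(gains, amps)):
            spec = ct.TaskSpec(
                2, "quiet_sway", 30.0, (amp, 0.0, 0.0),
                sway_band=(0.2, 0.6), n_sway_components=3, sway_noise_frac=0.0,
            )
            err = ct.SensorErrorModel(sway_gain=(g, 1.0, 1.0))
            rec = ct.generate_task_trial(spec, err, seed=100 + i)
            row, _ = ct.analyze_trial(rec)
            measured.append(row.rms[0])
            x = rec.truth_com.positions[:, 0]
            predicted.append(abs(g - 1) * x.std())
        rho = spearmanr(measured, predicted).statistic
        assert rho == pytest.approx(1.0)


class TestSummaries:
    def test_two_point_moments(self):
        rows = [
            AgreementRow(1, 1, STATUS_ANALYZED, (1.0, 4.0, 0.5)),
            AgreementRow(2, 1, STATUS_ANALYZED, (3.0, 2.0, 0.5)),
        ]
        summary = ct.summarize_by_task(rows)
        ts = summary.task_summaries[0]
        assert ts.n == 2
        assert ts.mean[0] == pytest.approx(2.0)
        assert ts.sd[0] == pytest.approx(np.sqrt(2.0))

    def test_zero_analyzed_task_has_undefined_moments(self):
        rows = [AgreementRow(1, 3, STATUS_COM_MISSING)]
        summary = ct.summarize_by_task(rows)
        ts = summary.task_summaries[0]
        assert ts.n == 0 and ts.mean is None and ts.sd is None

    def test_grand_aggregate_pools_trial_axis_values(self):
        rows = [
            AgreementRow(1, 1, STATUS_ANALYZED, (1.0, 2.0, 3.0)),
            AgreementRow(2, 2, STATUS_ANALYZED, (4.0, 5.0, 6.0)),
        ]
        summary = ct.summarize_by_task(rows)
        pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert summary.grand_mean_cm == pytest.approx(np.mean(pooled))
        assert summary.grand_sd_cm == pytest.approx(np.std(pooled, ddof=1))

    def test_row_contract(self):
        with pytest.raises(ct.ValidationError):
            AgreementRow(1, 1, STATUS_ANALYZED, None)
        with pytest.raises(ct.ValidationError):
            AgreementRow(1, 1, STATUS_COM_MISSING, (1.0, 1.0, 1.0))
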