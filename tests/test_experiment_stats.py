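"""Line-loss calibration, trace event detection, and the test battery."""
import numpy as np
import pytest
from dataclasses import replace

from retmech.experiment_stats import (LineLossModel, PerfusionRecord,
                                      PressureTrace, StatsError,
                                      calibrate_line_loss, compare_pressures,
                                      correct_trace, detect_events,
                                      normality_check, variance_check)
from retmech.synthetic_data import (GeneratorSpec, gen_open_tube,
                                    gen_perfusion_records, gen_pressure_trace)


class TestCalibration:
    def test_two_point_line(self):
        model = calibrate_line_loss([(0.0, 0.0), (100.0, 5.0)])
        assert model.slope == pytest.approx(0.05)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_from_noisy_open_tube(self):
        truth = LineLossModel(slope=0.03, intercept=0.5)
        flows = np.linspace(10, 200, 20)
        pairs = gen_open_tube(truth, flows, noise_sd=0.1, seed=7)
        model = calibrate_line_loss(pairs)
        assert model.slope == pytest.approx(truth.slope, abs=0.005)

    def test_single_flow_rejected(self):
        with pytest.raises(StatsError, match="distinct"):
            calibrate_line_loss([(50.0, 2.0), (50.0, 2.1)])


class TestCorrection:
    def _trace(self, pressures, flow=100.0):
        t = np.arange(len(pressures), dtype=float)
        return PressureTrace(t, np.asarray(pressures, float),
                             np.full(len(pressures), flow))

    def test_zero_loss_identity(self):
        tr = self._trace([10, 20, 30])
        out = correct_trace(tr, LineLossModel(0.0, 0.0))
        np.testing.assert_array_equal(out.pressure, tr.pressure)

    def test_constant_flow_uniform_shift(self):
        tr = self._trace([10, 20, 30], flow=100.0)
        out = correct_trace(tr, LineLossModel(0.05, 0.0))
        np.testing.assert_allclose(out.pressure, [5, 15, 25])

    def test_clipped_at_zero(self):
        tr = self._trace([2.0, 10.0])
        out = correct_trace(tr, LineLossModel(0.05, 0.0))
        assert out.pressure[0] == 0.0

    def test_trace_validation(self):
        with pytest.raises(StatsError, match="increasing"):
            PressureTrace(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2))
        with pytest.raises(StatsError, match="flow"):
            PressureTrace(np.array([0.0, 1.0]), np.zeros(2), np.array([1.0, -1.0]))


@pytest.fixture(scope="module")
def clean_record():
    return PerfusionRecord(eye_id="eye00", perfusion=40.0, settling=28.0, rh=39.0)


class TestEventDetection:
    def test_noise_free_round_trip_is_exact(self, clean_record):
        spec = GeneratorSpec(trace_noise_sd=0.0, line_loss=(0.0, 0.0))
        trace = gen_pressure_trace(clean_record, spec)
        rec = detect_events(trace)
        assert rec.perfusion == pytest.approx(clean_record.perfusion, abs=1e-6)
        assert rec.settling == pytest.approx(clean_record.settling, abs=1e-9)
        assert rec.rh == pytest.approx(clean_record.rh, abs=1e-6)

    def test_noisy_round_trip_with_line_loss(self, clean_record):
        spec = GeneratorSpec(seed=3, trace_noise_sd=0.5)
        trace = gen_pressure_trace(clean_record, spec)
        corrected = correct_trace(trace, spec.line_loss_model())
        rec = detect_events(corrected)
        assert rec.perfusion == pytest.approx(clean_record.perfusion, abs=0.5)
        assert rec.settling == pytest.approx(clean_record.settling, abs=0.5)
        assert rec.rh == pytest.approx(clean_record.rh, abs=0.5)

    def test_monotone_ramp_yields_missing_peak(self):
        t = np.arange(0, 120, 0.1)
        trace = PressureTrace(t, 0.5 * t, np.full(len(t), 100.0))
        with pytest.warns(UserWarning) as caught:
            rec = detect_events(trace)
        assert any("no perfusion peak" in str(w.message) for w in caught)
        assert rec.perfusion is None

    def test_plateau_only_trace(self):
        t = np.arange(0, 120, 0.1)
        trace = PressureTrace(t, np.full(len(t), 27.3), np.full(len(t), 100.0))
        with pytest.warns(UserWarning):
            rec = detect_events(trace)
        assert rec.settling == pytest.approx(27.3, abs=1e-9)

    def test_shift_equivariance(self, clean_record):
        spec = GeneratorSpec(seed=5, trace_noise_sd=0.3, line_loss=(0.0, 0.0))
        trace = gen_pressure_trace(clean_record, spec)
        shifted = replace(trace, pressure=trace.pressure + 10.0)
        r0, r1 = detect_events(trace), detect_events(shifted)
        assert r1.perfusion - r0.perfusion == pytest.approx(10.0, abs=1e-6)
        assert r1.settling - r0.settling == pytest.approx(10.0, abs=1e-6)
        assert r1.rh - r0.rh == pytest.approx(10.0, abs=1e-6)

    def test_csv_round_trip(self, tmp_path, clean_record):
        spec = GeneratorSpec(trace_noise_sd=0.0)
        trace = gen_pressure_trace(clean_record, spec)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = PressureTrace.from_csv(path)
        np.testing.assert_allclose(back.pressure, trace.pressure, atol=1e-4)
        assert len(back.events) == 1 and back.events[0][1] == "rh"


class TestComparisons:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_pressures(a, a.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)
        assert res.mean_difference == 0.0

    def test_printed_mean_difference(self):
        """Groups recentred to the printed means: RH onset 39.45 mmHg vs
        settling 28.61 mmHg gives the printed 10.84 mmHg difference."""
        rng = np.random.default_rng(0)
        rh = rng.normal(0, 11.43, 17)
        rh += 39.45 - rh.mean()
        settle = rng.normal(0, 15.40, 17)
        settle += 28.61 - settle.mean()
        res = compare_pressures(rh, settle)
        assert res.mean_difference == pytest.approx(10.84, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="zero variance"):
            compare_pressures([5.0, 5.0, 5.0], [7.0, 7.0])

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError, match="n >= 2"):
            compare_pressures([1.0], [2.0, 3.0])

    def test_power_against_printed_effect(self):
        """Drawing both groups at the printed means/SDs (n=17), the
        one-tailed test rejects more often than not."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            rh = rng.normal(39.45, 11.43, 17)
            settle = rng.normal(28.61, 15.40, 17)
            if compare_pressures(rh, settle).p < 0.05:
                hits += 1
        assert hits / n_rep > 0.5

    def test_type_one_error_calibration(self):
        """Null draws: one-tailed rejection rate at alpha=0.05 stays near
        nominal (vectorized pooled t over 2000 replicates)."""
        from scipy import stats as ss
        rng = np.random.default_rng(42)
        n, reps = 17, 2000
        a = rng.normal(30.0, 12.0, (reps, n))
        b = rng.normal(30.0, 12.0, (reps, n))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / n))
        p = ss.t.sf(t, df=2 * n - 2)
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestDistributionChecks:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(1)
        assert normality_check(rng.normal(size=10_000)) > 0.05

    def test_skewed_sample_fails(self):
        rng = np.random.default_rng(2)
        assert normality_check(rng.exponential(size=100)) < 0.05

    def test_small_n_rejected(self):
        with pytest.raises(StatsError, match="n >= 8"):
            normality_check([1.0] * 7)

    def test_variance_check_boundary(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert variance_check([g, list(g)]) == 1.0

    def test_variance_check_unequal(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1.0, 200)
        b = rng.normal(0, 5.0, 200)
        assert variance_check([a, b]) < 0.05
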