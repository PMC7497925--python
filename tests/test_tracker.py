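import numpy as np
import pytest

from tomosync.breathing import BreathingParameters, MotionTrace, generate_trace
from tomosync.delivery import DeliveryConfig, KvFix
from tomosync.metrics import delta_quantile, delta_rms, error_series
from tomosync.tracker import (
    FeatureSpec,
    _SurrogateHistory,
    compensation_residual,
    fit_correlation_model,
    localize_target,
    predict,
    read_tracking_log,
    run_tracking,
    write_tracking_log,
)
from conftest import case_breathing_parameters


def _linear_surrogate_trace(duration=120.0, slope=(1.5, 2.0, -0.8),
                            intercept=(0.0, 1.0, -2.0), seed=3,
                            amplitude=8.0):
    """Trace whose target axes are exact affine functions of the surrogate."""
    p = BreathingParameters(0, 0, 0, mean_period=4.0, duration=duration,
                            surrogate_mean_amplitude=amplitude, seed=seed,
                            drift_amplitude=0.0)
    tr = generate_trace(p)
    x = intercept[0] + slope[0] * tr.s
    y = intercept[1] + slope[1] * tr.s
    z = intercept[2] + slope[2] * tr.s
    return MotionTrace(times=tr.times, x=x, y=y, z=z, s=tr.s,
                       cum_phase=tr.cum_phase)


class TestLocalize:
    def test_noiseless_matches_trace(self, lung4_trace, rng):
        fix = localize_target(lung4_trace, 33.3, 0.0, rng)
        expected = [np.interp(33.3, lung4_trace.times, c)
                    for c in (lung4_trace.x, lung4_trace.y, lung4_trace.z)]
        assert np.allclose(fix.measured_position, expected)
        assert np.allclose(fix.measured_position, fix.true_position)

    def test_noise_is_unbiased(self, lung4_trace):
        rng = np.random.default_rng(5)
        sd = 0.3
        n = 10_000
        fixes = np.array([localize_target(lung4_trace, 20.0, sd, rng).measured_position
                          for _ in range(n)])
        se = sd / np.sqrt(n)
        true = localize_target(lung4_trace, 20.0, 0.0, rng).true_position
        assert np.all(np.abs(fixes.mean(axis=0) - true) < 3 * se)

    def test_seeded_reproducibility(self, lung4_trace):
        a = localize_target(lung4_trace, 10.0, 0.3, np.random.default_rng(9))
        b = localize_target(lung4_trace, 10.0, 0.3, np.random.default_rng(9))
        assert np.array_equal(a.measured_position, b.measured_position)

    def test_out_of_range(self, lung4_trace, rng):
        with pytest.raises(ValueError):
            localize_target(lung4_trace, 1e5, 0.0, rng)


def _history(trace, spec=None):
    spec = spec or FeatureSpec(mode="position")
    return _SurrogateHistory(trace.times, trace.s, spec)


class TestCorrelationFit:
    def test_exact_linear_recovery(self):
        trace = _linear_surrogate_trace()
        hist = _history(trace)
        rng = np.random.default_rng(0)
        times = np.linspace(5, 40, 6)
        fixes = [localize_target(trace, t, 0.0, rng) for t in times]
        model = fit_correlation_model(fixes, hist)
        assert model.slope_position == pytest.approx([1.5, 2.0, -0.8], abs=1e-9)
        assert model.intercept == pytest.approx([0.0, 1.0, -2.0], abs=1e-9)
        assert model.fit_residual_rms < 1e-9

    def test_constant_target_constant_surrogate_fallback(self):
        t = np.arange(0, 30.001, 0.0125)
        const = np.full_like(t, 2.0)
        trace = MotionTrace(times=t, x=const, y=const, z=const,
                            s=np.zeros_like(t))
        hist = _history(trace)
        rng = np.random.default_rng(0)
        fixes = [localize_target(trace, tt, 0.0, rng) for tt in np.linspace(2, 25, 8)]
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_correlation_model(fixes, hist)
        assert model.intercept_only
        assert model.intercept == pytest.approx([2.0, 2.0, 2.0])

    def test_noisy_fit_matches_normal_equations_oracle(self):
        trace = _linear_surrogate_trace(duration=300.0)
        hist = _history(trace)
        rng = np.random.default_rng(42)
        times = np.linspace(5, 290, 50)
        fixes = [localize_target(trace, t, 0.3, rng) for t in times]
        model = fit_correlation_model(fixes, hist)
        # independent oracle: explicit normal equations
        X = np.column_stack([np.ones(50), np.interp(times, trace.times, trace.s)])
        Y = np.array([f.measured_position for f in fixes])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(model.coef[:2], beta, atol=1e-8)

    def test_predict_examples(self):
        spec = FeatureSpec(mode="position")
        from tomosync.tracker import CorrelationModel
        model = CorrelationModel(coef=np.array([[1.0, 2.0, 3.0],
                                                [0.0, 2.0, 0.0]]),
                                 spec=spec, fit_time=0.0, n_fixes_used=5,
                                 fit_residual_rms=0.0)
        out = predict(model, np.array([[1.0, 3.0]]))
        assert np.allclose(out, [[1.0, 8.0, 3.0]])


class TestRunTracking:
    def test_static_trace_tracks_exactly(self):
        t = np.arange(0, 90.001, 0.0125)
        zeros = np.zeros_like(t)
        trace = MotionTrace(times=t, x=zeros, y=zeros, z=zeros, s=zeros)
        cfg = DeliveryConfig(treatment_duration=80.0, kv_noise_sd=0.0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            tracked = run_tracking(trace, cfg, surrogate_source="surrogate")
        err = error_series(tracked)
        assert err.max() < 1e-12

    def test_perfect_correlation_limit(self):
        trace = _linear_surrogate_trace(duration=130.0)
        cfg = DeliveryConfig(treatment_duration=120.0, kv_noise_sd=0.0)
        tracked = run_tracking(trace, cfg, surrogate_source="surrogate")
        assert delta_rms(error_series(tracked)) < 1e-6

    def test_log_grid_spacing(self, lung4_trace):
        cfg = DeliveryConfig(treatment_duration=100.0)
        tracked = run_tracking(lung4_trace, cfg, surrogate_source="phantom")
        assert np.allclose(np.diff(tracked.times), cfg.led_interval)
        assert not tracked.model_valid[0]
        assert tracked.model_valid[-1]

    def test_noise_monotonically_degrades_tracking(self):
        p = case_breathing_parameters("Lung 4", duration=200.0, seed=21,
                                      drift_amplitude=0.0)
        trace = generate_trace(p)
        means = []
        for noise in (0.0, 1.0, 3.0):
            rms = []
            for seed in range(4):
                cfg = DeliveryConfig(treatment_duration=180.0, kv_noise_sd=noise)
                tracked = run_tracking(trace, cfg, surrogate_source="phantom",
                                       seed=seed)
                rms.append(delta_rms(error_series(tracked)))
            means.append(np.mean(rms))
        assert means[0] <= means[1] <= means[2]

    def test_surrogate_phase_shift_degrades_tracking(self):
        # +20% surrogate phase shift (Lung 5e analog) tracks worse than an
        # in-phase surrogate (Lung 5a analog)
        q95 = {}
        for shift in (0.0, 0.20):
            p = case_breathing_parameters("Lung 5", duration=240.0, seed=17,
                                          surrogate_mean_amplitude=5.0,
                                          surrogate_phase_shift=shift)
            trace = generate_trace(p)
            cfg = DeliveryConfig(treatment_duration=230.0)
            tracked = run_tracking(trace, cfg, surrogate_source="surrogate",
                                   seed=3)
            q95[shift] = delta_quantile(error_series(tracked), 0.95)
        assert q95[0.20] > q95[0.0]

    def test_aliased_imaging_degrades_tracking(self):
        # ~1.0 image per respiration aliases with breathing and tracks
        # worse than ~1.3 images per respiration
        p = case_breathing_parameters("Liver 1", duration=250.0, seed=13,
                                      period_sd=0.0, amplitude_rel_sd=0.0,
                                      drift_amplitude=0.0)
        trace = generate_trace(p)
        rms = {}
        for kv in (4, 5):
            cfg = DeliveryConfig(treatment_duration=240.0, gantry_period=11.8,
                                 kv_per_rotation=kv)
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    tracked = run_tracking(trace, cfg, surrogate_source="phantom",
                                           seed=2)
            rms[kv] = delta_rms(error_series(tracked))
        assert rms[4] > rms[5]

    def test_short_trace_rejected(self, lung4_trace):
        cfg = DeliveryConfig(treatment_duration=1e4)
        with pytest.raises(ValueError):
            run_tracking(lung4_trace, cfg)


class TestCompensationResidual:
    @staticmethod
    def _tracked(true, predicted, angles, valid=None):
        n = len(angles)
        times = 0.0125 * np.arange(n)
        valid = np.ones(n, dtype=bool) if valid is None else valid
        from tomosync.tracker import TrackedTrace
        return TrackedTrace(times=times, predicted=predicted, true=true,
                            model_valid=valid, gantry_angle=np.asarray(angles, float))

    def test_zero_error_zero_residual(self):
        pos = np.tile([1.0, -2.0, 3.0], (4, 1))
        tracked = self._tracked(pos, pos.copy(), [0, 45, 90, 180])
        assert np.allclose(compensation_residual(tracked), 0.0)

    def test_pure_y_error_passes_through(self):
        true = np.tile([0.0, 2.0, 0.0], (3, 1))
        pred = np.zeros((3, 3))
        tracked = self._tracked(true, pred, [0, 90, 270])
        res = compensation_residual(tracked)
        assert np.allclose(np.linalg.norm(res, axis=1), 2.0)

    def test_along_beam_projection_geometry(self):
        # an untracked pure-Z offset vanishes at gantry 0 (along the beam)
        # and survives fully at gantry 90 (perpendicular to the beam)
        true = np.tile([0.0, 0.0, 5.0], (2, 1))
        pred = np.zeros((2, 3))
        tracked = self._tracked(true, pred, [0, 90])
        res = compensation_residual(tracked, along_beam_weight=0.0)
        assert np.allclose(res[0], 0.0, atol=1e-12)
        assert np.allclose(res[1], [0.0, 0.0, 5.0], atol=1e-12)

    def test_warmup_residual_is_full_displacement(self):
        true = np.tile([1.0, 2.0, 3.0], (2, 1))
        pred = np.zeros((2, 3))
        tracked = self._tracked(true, pred, [0, 0],
                                valid=np.array([False, True]))
        res = compensation_residual(tracked)
        assert np.allclose(res[0], [1.0, 2.0, 3.0])


def test_tracking_log_round_trip(tmp_path, lung4_trace):
    cfg = DeliveryConfig(treatment_duration=60.0)
    tracked = run_tracking(lung4_trace, cfg, surrogate_source="phantom")
    path = tmp_path / "log.csv"
    write_tracking_log(tracked, path)
    back = read_tracking_log(path)
    assert np.array_equal(back.model_valid, tracked.model_valid)
    assert np.allclose(back.predicted, tracked.predicted, atol=5e-7)
    assert np.allclose(back.true, tracked.true, atol=5e-7)
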