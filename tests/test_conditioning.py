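"""Conditioning ops: EMG, quintic smoothing, sono conversion, buckle calibration."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawfl import (
    CalibrationModel,
    ConfigurationError,
    FilterSpec,
    MissingChannelError,
    SonoConfig,
    Trace,
    Trial,
    apply_buckle_calibration,
    condition_emg,
    fit_buckle_calibration,
    integrate_emg,
    resample_and_sync,
    smooth_quintic,
    sono_to_length,
)


class TestConditionEmg:
    def test_constant_trace_maps_to_zero(self):
        tr = Trace(np.full(1000, 3.7), 1000.0)
        out = condition_emg(tr, (0.0, 0.5))
        assert np.allclose(out.values, 0.0)

    def test_clean_sinusoid_rectified_mean(self):
        # mean of |A sin| over whole periods is 2A/pi
        t = np.arange(0, 1.0, 1 / 4000)
        tr = Trace(2.0 * np.sin(2 * np.pi * 10 * t), 4000.0)
        out = condition_emg(tr, (0.0, tr.t_end))
        assert np.mean(out.values) == pytest.approx(2 * 2.0 / np.pi, rel=1e-3)

    def test_rectification_idempotent_on_nonnegative_zero_baseline(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.standard_normal(500))
        vals -= 0  # zero baseline by construction below
        tr = Trace(np.concatenate([np.zeros(500), vals]), 1000.0)
        out = condition_emg(tr, (0.0, 0.4))
        assert np.allclose(out.values[500:], vals)

    def test_output_nonnegative_with_filter(self):
        rng = np.random.default_rng(2)
        tr = Trace(rng.standard_normal(4000), 4000.0)
        out = condition_emg(tr, (0.0, 0.2), FilterSpec())
        assert np.all(out.values >= 0)

    def test_empty_baseline_window_rejected(self):
        tr = Trace(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            condition_emg(tr, (2.0, 3.0))

    def test_filter_order_exceeding_trace_rejected(self):
        tr = Trace(np.zeros(50), 1000.0)
        with pytest.raises(ConfigurationError):
            condition_emg(tr, (0.0, 0.04), FilterSpec(numtaps=201))


class TestIntegrateEmg:
    def test_constant_one_mv_over_100ms(self):
        tr = Trace(np.ones(4000), 4000.0)
        assert integrate_emg(tr, (0.1, 0.2)) == pytest.approx(0.1, rel=1e-9)

    def test_linear_in_amplitude(self):
        rng = np.random.default_rng(3)
        v = np.abs(rng.standard_normal(2000))
        a = integrate_emg(Trace(v, 1000.0), (0.2, 1.5))
        b = integrate_emg(Trace(2 * v, 1000.0), (0.2, 1.5))
        assert b == pytest.approx(2 * a, rel=1e-12)

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additive_over_adjacent_windows(self, split):
        rng = np.random.default_rng(4)
        tr = Trace(np.abs(rng.standard_normal(1000)), 1000.0)
        t_mid = split * tr.t_end
        whole = integrate_emg(tr, (0.0, tr.t_end))
        parts = integrate_emg(tr, (0.0, t_mid)) + integrate_emg(tr, (t_mid, tr.t_end))
        assert parts == pytest.approx(whole, rel=1e-9, abs=1e-12)

    def test_analytic_burst_area(self):
        # Hann-shaped rectified burst: integral = amp * dur / 2
        rate, dur, amp = 4000.0, 0.25, 1.5
        t = np.arange(0, 1.0, 1 / rate)
        env = np.where(
            (t >= 0.3) & (t <= 0.3 + dur),
            amp * 0.5 * (1 - np.cos(2 * np.pi * (t - 0.3) / dur)),
            0.0,
        )
        got = integrate_emg(Trace(env, rate), (0.3, 0.3 + dur))
        assert got == pytest.approx(amp * dur / 2, rel=1e-3)

    def test_inverted_window_rejected(self):
        tr = Trace(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            integrate_emg(tr, (0.5, 0.1))


class TestSmoothQuintic:
    def test_reproduces_cubic_polynomial(self):
        x = np.arange(80) / 10
        tr = Trace(0.3 * x**3 - x**2 + 2 * x + 1, 10.0)
        out = smooth_quintic(tr, 0.03)
        assert np.max(np.abs(out.values - tr.values)) <= 1e-8

    def test_reproduces_linear_ramp(self):
        tr = Trace(np.linspace(2, 14, 300), 520.0)
        out = smooth_quintic(tr, 0.02)
        assert np.max(np.abs(out.values - tr.values)) <= 1e-6

    def test_reduces_white_noise_variance(self):
        reduced = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            tr = Trace(rng.standard_normal(400), 100.0)
            out = smooth_quintic(tr, 0.05)
            reduced += np.var(out.values) < np.var(tr.values)
        assert reduced == 50

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            smooth_quintic(Trace(np.arange(6.0), 10.0), 0.02)


class TestSonoToLength:
    def test_arithmetic_of_conversion(self):
        # gain 5 mm/V, 2.4 V -> 12 mm spanned (typical crystal spacing)
        tr = Trace(np.full(10, 2.4), 520.0)
        cfg = SonoConfig(gain=5.0, epoxy_offset=0.0, segment_factor=1.0, spline_sd=None)
        out = sono_to_length(tr, cfg)
        assert np.allclose(out.values, 12.0)
        assert out.units == "mm"

    def test_segment_factor_scales_to_whole_fascicle(self):
        tr = Trace(np.full(10, 2.4), 520.0)
        cfg = SonoConfig(gain=5.0, segment_factor=1.25, spline_sd=None)
        assert np.allclose(sono_to_length(tr, cfg).values, 15.0)

    def test_epoxy_offset_subtracted_before_segment_scaling(self):
        tr = Trace(np.full(10, 2.4), 520.0)
        cfg = SonoConfig(gain=5.0, epoxy_offset=0.8, segment_factor=1.25, spline_sd=None)
        assert np.allclose(sono_to_length(tr, cfg).values, (12.0 - 0.8) * 1.25)

    def test_dropouts_masked_not_interpolated(self):
        vals = np.full(40, 2.0)
        vals[10] = -1.0
        tr = Trace(vals, 520.0)
        cfg = SonoConfig(gain=5.0, epoxy_offset=0.0, segment_factor=1.0, spline_sd=None)
        with pytest.warns(UserWarning):
            out = sono_to_length(tr, cfg)
        assert np.isnan(out.values[10])
        assert np.all(np.isfinite(np.delete(out.values, 10)))

    def test_spline_sd_outside_band_rejected(self):
        with pytest.raises(ConfigurationError):
            SonoConfig(gain=5.0, spline_sd=0.5)


class TestBuckleCalibration:
    def test_noiseless_collinear_pair_exact(self):
        f = np.linspace(0, 6, 400)
        v = 0.02 * f + 0.05
        model = fit_buckle_calibration(
            [(Trace(v, 4000.0), Trace(f, 4000.0))], [(0.0, 399 / 4000)]
        )
        assert model.slope == pytest.approx(0.02, rel=1e-12)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_three_point_ols(self):
        f = np.array([0.0, 1.0, 2.0])
        v = np.array([0.0, 2.0, 4.0])
        model = fit_buckle_calibration([(Trace(v, 1.0), Trace(f, 1.0))], [(0.0, 2.0)])
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_model_slope_is_mean_of_pair_slopes(self):
        f = np.linspace(0, 5, 100)
        pairs = [
            (Trace(0.02 * f, 100.0), Trace(f, 100.0)),
            (Trace(0.04 * f, 100.0), Trace(f, 100.0)),
        ]
        model = fit_buckle_calibration(pairs, [(0.0, 0.99)] * 2)
        assert model.slope == pytest.approx(0.03, rel=1e-12)

    def test_zero_variance_force_rejected(self):
        f = np.full(100, 2.0)
        with pytest.raises(ValueError):
            fit_buckle_calibration([(Trace(f, 100.0), Trace(f, 100.0))], [(0.0, 0.99)])

    def test_apply_requires_positive_slope(self):
        model = CalibrationModel(slope=0.02, intercept=0.0, r2=1.0, n_samples=10)
        bad = CalibrationModel(slope=-0.02, intercept=0.0, r2=1.0, n_samples=10)
        tr = Trace(np.zeros(100), 100.0)
        apply_buckle_calibration(tr, model, (0.0, 0.5))
        with pytest.raises(ConfigurationError):
            apply_buckle_calibration(tr, bad, (0.0, 0.5))

    def test_rest_window_maps_to_zero_newtons(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([np.full(200, 0.13), 0.13 + rng.uniform(0, 1, 200)])
        model = CalibrationModel(slope=0.02, intercept=0.13, r2=1.0, n_samples=10)
        out = apply_buckle_calibration(Trace(v, 100.0), model, (0.0, 1.99))
        assert np.mean(out.window_values(0.0, 1.99)) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_round_trip(self, truth):
        from jawfl import simulate_calibration_pair

        trials = simulate_calibration_pair(truth, 4, noise=0.0, seed=0)
        pairs = [(t.channel("buckle_voltage"), t.channel("force")) for t in trials]
        model = fit_buckle_calibration(pairs, [t.truth["rise_window"] for t in trials])
        assert model.slope == pytest.approx(truth.buckle_slope, rel=1e-9)
        gauge = trials[0].channel("buckle_voltage")
        force_true = trials[0].channel("force").values
        rest = (0.05, 0.25)
        out = apply_buckle_calibration(gauge, model, rest)
        rest_force = np.mean(trials[0].channel("force").window_values(*rest))
        rmse = np.sqrt(np.mean((out.values - (force_true - rest_force)) ** 2))
        assert rmse <= 1e-9


class TestResampleAndSync:
    @staticmethod
    def _trial_with_sync(extra=None, rate=4000.0):
        t = np.arange(0, 1.0, 1 / rate)
        sync = ((t >= 0.1) & (t < 0.15)).astype(float)
        channels = {"sync": Trace(sync, rate)}
        if extra:
            channels.update(extra)
        return Trial(channels=channels)

    def test_low_rate_ramp_upsampled_exactly(self):
        t520 = np.arange(0, 1.0, 1 / 520)
        ramp = Trace(2.0 + 3.0 * t520, 520.0)
        trial = self._trial_with_sync({"sono_voltage": ramp})
        out = resample_and_sync(trial, 4000.0)
        ch = out.channel("sono_voltage")
        expected = 2.0 + 3.0 * ch.times()
        assert np.max(np.abs(ch.values - expected)) <= 1e-6 * np.ptp(ramp.values)
        assert ch.rate == 4000.0

    def test_identity_at_same_rate(self):
        rng = np.random.default_rng(5)
        sig = Trace(rng.standard_normal(4000), 4000.0)
        trial = self._trial_with_sync({"emg": sig})
        out = resample_and_sync(trial, 4000.0)
        assert np.allclose(out.channel("emg").values, sig.values, atol=1e-12)

    def test_sync_edge_lands_on_grid_sample(self):
        trial = self._trial_with_sync()
        out = resample_and_sync(trial, 2000.0)
        sync = out.channel("sync")
        edge_t = sync.times()[int(np.argmax(sync.values >= 0.5))]
        # the edge time is representable on the target grid within one sample
        k = (edge_t - sync.t0) * 2000.0
        assert abs(k - round(k)) < 1e-6

    def test_missing_sync_rejected(self):
        trial = Trial(channels={"emg": Trace(np.zeros(100), 100.0)})
        with pytest.raises(MissingChannelError):
            resample_and_sync(trial, 1000.0)
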