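import numpy as np
import pytest

from fiberphot import (DetrendModel, Recording, align_nearest, append_rows,
                       apply_detrend, fit_detrend, linear_scale,
                       lowpass_downsample, ratio_channel)


def rec_from(time, rate=None, **channels):
    time = np.asarray(time, dtype=float)
    rate = rate or 1.0 / np.median(np.diff(time))
    return Recording("r", time, {k: np.asarray(v, dtype=float) for k, v in channels.items()}, rate)


class TestAlignNearest:
    def test_hand_nearest_neighbor(self):
        other = rec_from([0.0, 1.0, 2.0], beh=[10.0, 20.0, 30.0])
        base = rec_from([0.4, 0.6, 1.9], sig=[0.0, 0.0, 0.0])
        out, _ = align_nearest(base, other, ["beh"])
        assert np.allclose(out.channels["beh"], [10.0, 20.0, 30.0])

    def test_midpoint_tie_takes_earlier(self):
        other = rec_from([0.0, 1.0], beh=[10.0, 20.0])
        base = rec_from([0.5], rate=1.0, sig=[0.0])
        out, _ = align_nearest(base, other, ["beh"])
        assert out.channels["beh"][0] == 10.0

    def test_identical_axes_identity(self):
        other = rec_from([0.0, 1.0, 2.0], beh=[1.0, 2.0, 3.0])
        base = rec_from([0.0, 1.0, 2.0], sig=[0.0, 0.0, 0.0])
        out, coverage = align_nearest(base, other, ["beh"])
        assert np.array_equal(out.channels["beh"], other.channels["beh"])
        assert coverage["clamped"]["beh"] == 0

    def test_out_of_span_clamps_and_reports(self):
        other = rec_from([1.0, 2.0], beh=[10.0, 20.0])
        base = rec_from([0.0, 1.5, 3.0], sig=[0.0] * 3)
        with pytest.warns(UserWarning, match="span"):
            out, coverage = align_nearest(base, other, ["beh"])
        assert out.channels["beh"][0] == 10.0 and out.channels["beh"][2] == 20.0
        assert coverage["clamped"]["beh"] == 2

    def test_name_collision_requires_rename(self):
        other = rec_from([0.0, 1.0], sig=[1.0, 2.0])
        base = rec_from([0.0, 1.0], sig=[0.0, 0.0])
        with pytest.raises(ValueError, match="collision"):
            align_nearest(base, other, ["sig"])
        out, _ = align_nearest(base, other, ["sig"], rename={"sig": "sig_beh"})
        assert "sig_beh" in out.channels


class TestAppendRows:
    def test_shift_arithmetic(self):
        a = rec_from([0.0, 1.0, 2.0], x=[1.0, 2.0, 3.0])
        b = rec_from([0.0, 1.0, 2.0], x=[4.0, 5.0, 6.0])
        out = append_rows(a, b, gap_s=0.0)
        assert np.allclose(out.time, [0, 1, 2, 3, 4, 5])  # b starts at 2 + 1/1
        assert np.allclose(out.channels["x"], [1, 2, 3, 4, 5, 6])

    def test_gap_added(self):
        a = rec_from([0.0, 1.0], x=[1.0, 1.0])
        b = rec_from([5.0, 6.0], x=[2.0, 2.0])
        out = append_rows(a, b, gap_s=10.0)
        assert out.time[2] == pytest.approx(1.0 + 10.0 + 1.0)

    def test_append_empty_is_identity(self):
        a = rec_from([0.0, 1.0], x=[1.0, 2.0])
        empty = Recording("e", np.array([]), {"x": np.array([])}, 1.0)
        assert append_rows(a, empty).channels["x"].tolist() == [1.0, 2.0]

    def test_segment_counts_and_means_preserved(self):
        a = rec_from([0.0, 1.0, 2.0], x=[1.0, 2.0, 3.0])
        b = rec_from([0.0, 1.0], x=[10.0, 20.0])
        out = append_rows(a, b)
        assert out.n_samples == 5
        assert out.channels["x"][:3].mean() == pytest.approx(2.0)
        assert out.channels["x"][3:].mean() == pytest.approx(15.0)

    def test_channel_mismatch_lists_difference(self):
        a = rec_from([0.0, 1.0], x=[1.0, 2.0])
        b = rec_from([0.0, 1.0], y=[1.0, 2.0])
        with pytest.raises(ValueError, match="'x'"):
            append_rows(a, b)


class TestRatioChannel:
    def test_num_equals_den_gives_ones(self):
        r = rec_from([0.0, 1.0], a=[2.0, 3.0], b=[2.0, 3.0])
        out = ratio_channel(r, "a", "b", "ratio")
        assert np.allclose(out.channels["ratio"], 1.0)

    def test_elementwise_and_zero_sample(self):
        r = rec_from([0.0, 1.0, 2.0], a=[2.0, 4.0, 1.0], b=[1.0, 2.0, 0.0])
        out = ratio_channel(r, "a", "b", "q")
        assert np.allclose(out.channels["q"][:2], [2.0, 2.0])
        assert np.isnan(out.channels["q"][2])


class TestLowpassDownsample:
    def test_constant_preserved_any_factor(self):
        t = np.arange(1000) / 100.0
        r = rec_from(t, rate=100.0, x=np.full(1000, 3.7))
        out = lowpass_downsample(r, "x", cutoff_hz=5.0, factor=4)
        assert np.allclose(out.channels["x"], 3.7)
        assert out.n_samples == 250
        assert out.rate_hz == pytest.approx(25.0)

    def test_sine_attenuated_below_cutoff(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        r = rec_from(t, rate=100.0, x=x)
        out = lowpass_downsample(r, "x", cutoff_hz=2.0, factor=1)
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(out.channels["x"] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_factor_one_keeps_time_axis(self):
        t = np.arange(100) / 10.0
        r = rec_from(t, rate=10.0, x=np.sin(t))
        out = lowpass_downsample(r, "x", cutoff_hz=2.0, factor=1)
        assert np.array_equal(out.time, t)

    def test_cutoff_at_nyquist_rejected(self):
        r = rec_from(np.arange(100) / 10.0, rate=10.0, x=np.zeros(100))
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_downsample(r, "x", cutoff_hz=5.0, factor=2)


class TestLinearScale:
    def test_exact_affine_recovery(self):
        x = np.linspace(0, 10, 50)
        r = rec_from(np.arange(50.0), src=x, tgt=3.0 * x + 1.0)
        out, fit = linear_scale(r, "src", "tgt", "scaled")
        assert np.allclose(out.channels["scaled"], r.channels["tgt"], atol=1e-10)
        assert fit.slope == pytest.approx(3.0) and fit.intercept == pytest.approx(1.0)

    def test_self_scaling_identity(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        r = rec_from(np.arange(4.0), src=x, tgt=x)
        _, fit = linear_scale(r, "src", "tgt", "o")
        assert fit.slope == pytest.approx(1.0) and fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_regression(self, rng):
        x = rng.normal(size=200)
        y = 2.0 * x + 0.5 + rng.normal(scale=0.3, size=200)
        r = rec_from(np.arange(200.0), src=x, tgt=y)
        _, fit = linear_scale(r, "src", "tgt", "o")
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-12)

    def test_zero_variance_source_rejected(self):
        r = rec_from(np.arange(4.0), src=np.ones(4), tgt=np.arange(4.0))
        with pytest.raises(ValueError, match="variance"):
            linear_scale(r, "src", "tgt", "o")


class TestDetrend:
    def test_noiseless_exponential_recovery(self):
        t = np.arange(0, 600.0, 0.5)
        y = 5.0 * np.exp(-0.01 * t) + 2.0
        r = rec_from(t, rate=2.0, sig=y)
        model = fit_detrend(r, "sig", kind="exponential")
        assert model.params["a"] == pytest.approx(5.0, rel=1e-6)
        assert model.params["b"] == pytest.approx(0.01, rel=1e-6)
        assert model.params["c"] == pytest.approx(2.0, rel=1e-6)

    def test_linear_exact(self):
        t = np.arange(0, 100.0)
        r = rec_from(t, sig=4.0 - 0.002 * t)
        model = fit_detrend(r, "sig", kind="linear")
        assert model.params["a"] == pytest.approx(4.0)
        assert model.params["b"] == pytest.approx(-0.002)

    def test_manual_params_bypass_fitting(self):
        r = rec_from(np.arange(10.0), sig=np.arange(10.0))
        model = fit_detrend(r, "sig", kind="exponential",
                            params={"a": 1.0, "b": 0.5, "c": 2.0})
        assert not model.fitted
        assert model.params == {"a": 1.0, "b": 0.5, "c": 2.0}

    def test_negative_decay_rate_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            DetrendModel("exponential", {"a": 1.0, "b": -0.1, "c": 0.0})

    def test_residual_plus_prediction_conserves_raw(self, rng):
        t = np.arange(0, 300.0, 0.2)
        y = 8.0 * np.exp(-0.005 * t) + 3.0 + rng.normal(scale=0.2, size=t.size)
        r = rec_from(t, rate=5.0, sig=y)
        model = fit_detrend(r, "sig", kind="exponential")
        out = apply_detrend(r, "sig", model, out="resid", keep_prediction=True)
        recon = out.channels["resid"] + out.channels["resid_prediction"]
        assert np.array_equal(recon, y)  # exact elementwise conservation

    def test_detrending_own_prediction_gives_zero(self):
        t = np.arange(0, 100.0)
        model = DetrendModel("exponential", {"a": 5.0, "b": 0.02, "c": 1.0}, fitted=False)
        r = rec_from(t, sig=model.predict(t))
        out = apply_detrend(r, "sig", model, out="resid")
        assert np.allclose(out.channels["resid"], 0.0, atol=1e-12)

    def test_residual_trend_removed_from_bleached_transients(self, rng):
        from fiberphot import SynthSpec, Transient, make_recording
        spec = SynthSpec(duration_s=600.0, rate_hz=10.0, baseline_mu=50.0,
                         noise_sd=0.5, bleach_amplitude=30.0, bleach_rate=1 / 200.0,
                         transients=[Transient(o, 5.0, 0.2, 1.5, 5.0)
                                     for o in (60.0, 200.0, 400.0)],
                         ttl_schedule=[], seed=7)
        rec, truth = make_recording(spec)
        model = fit_detrend(rec, "signal", kind="exponential")
        out = apply_detrend(rec, "signal", model, out="resid")
        slope_raw = np.polyfit(rec.time, rec.channels["signal"], 1)[0]
        slope_resid = np.polyfit(out.time, out.channels["resid"], 1)[0]
        assert abs(slope_resid) < 1e-4 * abs(slope_raw) + 1e-6

    def test_snr20_parameter_recovery_within_5pct(self, rng):
        t = np.arange(0, 900.0, 0.1)
        a, b, c = 40.0, 1 / 300.0, 100.0
        y = a * np.exp(-b * t) + c + rng.normal(scale=2.0, size=t.size)  # SNR = 20
        r = rec_from(t, rate=10.0, sig=y)
        model = fit_detrend(r, "sig", kind="exponential")
        assert model.params["a"] == pytest.approx(a, rel=0.05)
        assert model.params["b"] == pytest.approx(b, rel=0.05)
        assert model.params["c"] == pytest.approx(c, rel=0.05)
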