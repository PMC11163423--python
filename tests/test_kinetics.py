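"""Leakage normalization, smoothing, sigmoid fitting, and lipid mixing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bilayerkit as bk
from bilayerkit.errors import (
    AlignmentError,
    DegenerateReferenceError,
    ValidationError,
)


def _traces(times, it, i0, imax):
    return (
        bk.FluorescenceTrace(times, it, "sample"),
        bk.FluorescenceTrace(times, i0, "baseline"),
        bk.FluorescenceTrace(times, imax, "triton"),
    )


class TestNormalizeLeakage:
    @pytest.mark.parametrize(
        "it_level, expected",
        [(350.0, 50.0), (100.0, 0.0), (600.0, 100.0)],
    )
    def test_fixed_levels(self, it_level, expected):
        times = np.linspace(0.5, 10, 50)
        s, b, t = _traces(times, np.full(50, it_level), np.full(50, 100.0), np.full(50, 600.0))
        out = bk.normalize_leakage(s, b, t)
        assert np.allclose(out, expected)

    def test_mismatched_time_axes_rejected(self):
        s, b, t = _traces(np.linspace(0.5, 10, 50), *[np.full(50, 1.0)] * 3)
        b2 = bk.FluorescenceTrace(np.linspace(0.6, 10.1, 50), np.full(50, 1.0), "baseline")
        with pytest.raises(AlignmentError):
            bk.normalize_leakage(s, b2, t)

    def test_degenerate_reference_rejected(self):
        times = np.linspace(0.5, 10, 50)
        s, b, t = _traces(times, np.full(50, 1.0), np.full(50, 5.0), np.full(50, 5.0))
        with pytest.raises(DegenerateReferenceError):
            bk.normalize_leakage(s, b, t)

    def test_negative_values_reported_not_clipped(self):
        times = np.linspace(0.5, 10, 50)
        s, b, t = _traces(times, np.full(50, 90.0), np.full(50, 100.0), np.full(50, 600.0))
        out = bk.normalize_leakage(s, b, t)
        assert np.all(out < 0)

    @given(gain=st.floats(0.1, 10.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, gain, offset):
        """Rescaling all three channels by one gain/offset leaves leakage unchanged."""
        times = np.linspace(0.5, 20, 100)
        it = 100.0 + 400.0 / (1.0 + np.exp(-(times - 5.0)))
        s, b, t = _traces(times, it, np.full(100, 100.0), np.full(100, 600.0))
        ref = bk.normalize_leakage(s, b, t)
        s2, b2, t2 = _traces(times, gain * it + offset, gain * 100.0 + offset + 0 * times,
                             gain * 600.0 + offset + 0 * times)
        out = bk.normalize_leakage(s2, b2, t2)
        assert np.allclose(out, ref, atol=1e-8)


class TestSmooth3:
    def test_direct_arithmetic(self):
        out = bk.smooth3(pd.Series([0.0, 3.0, 0.0]))
        assert np.allclose(out, [1.5, 1.0, 1.5])

    def test_constants_and_ramps_preserved(self):
        const = bk.smooth3(pd.Series(np.full(10, 7.0)))
        assert np.allclose(const, 7.0)
        ramp = pd.Series(np.linspace(0, 9, 10))
        out = bk.smooth3(ramp)
        assert np.allclose(out.iloc[1:-1], ramp.iloc[1:-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            bk.smooth3(pd.Series([1.0, 2.0]))

    def test_repeated_smoothing_reduces_noise_variance(self, rng):
        noise = pd.Series(rng.normal(size=500))
        v0 = float(np.var(noise))
        once = bk.smooth3(noise)
        twice = bk.smooth3(once)
        assert np.var(once) < v0
        assert np.var(twice) < np.var(once)


class TestFitSigmoid:
    @pytest.mark.parametrize(
        "a0, k, tc, t_end",
        [(99.1, 0.52, 0.87, 40.0), (50.0, 0.2, 10.0, 60.0), (41.42, 0.20, 20.60, 80.0)],
    )
    def test_noiseless_round_trip(self, a0, k, tc, t_end):
        spec = bk.LeakageTraceSpec(a0=a0, k=k, tc=tc, t_end=t_end)
        series = bk.normalize_leakage(*bk.gen_leakage_traces(spec))
        fit = bk.fit_sigmoid(series, smooth=False)
        assert fit.converged
        assert fit.a0 == pytest.approx(a0, rel=1e-4)
        assert fit.k == pytest.approx(k, rel=1e-4)
        assert fit.tc == pytest.approx(tc, rel=1e-4)

    def test_smoothed_fit_close_to_truth(self, popc_leakage_traces):
        _, traces = popc_leakage_traces
        fit = bk.fit_sigmoid(bk.normalize_leakage(*traces), smooth=True)
        assert fit.converged
        assert fit.k == pytest.approx(0.52, rel=5e-3)
        assert fit.tc == pytest.approx(0.87, rel=5e-3)

    def test_flat_trace_non_identifiable(self):
        """A plateau-only trace yields its level and NaN rate, like an N.D. entry."""
        times = np.linspace(0.5, 40, 300)
        series = pd.Series(np.full(300, 3.05), index=times)
        fit = bk.fit_sigmoid(series)
        assert not fit.converged
        assert fit.a0 == pytest.approx(3.05, abs=0.01)
        assert np.isnan(fit.k) and np.isnan(fit.tc)

    def test_rise_before_first_sample_non_identifiable(self):
        spec = bk.LeakageTraceSpec(a0=3.05, k=45.0, tc=0.0, t_end=40.0)
        fit = bk.fit_sigmoid(bk.normalize_leakage(*bk.gen_leakage_traces(spec)))
        assert not fit.converged
        assert fit.a0 == pytest.approx(3.05, abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            bk.fit_sigmoid(pd.Series([1.0, 2, 3, 4, 5], index=np.arange(5.0)))

    def test_noisy_recovery_median_rate_error(self):
        """Across seeded noisy traces the median relative rate error stays < 10 %."""
        errs = []
        for seed in range(100):
            spec = bk.LeakageTraceSpec(
                a0=60.0, k=0.3, tc=8.0, t_end=40.0, dt=0.25,
                noise_sd=0.02 * 1100.0, seed=seed,
            )
            series = bk.normalize_leakage(*bk.gen_leakage_traces(spec))
            fit = bk.fit_sigmoid(series)
            if fit.converged:
                errs.append(abs(fit.k - 0.3) / 0.3)
            else:
                errs.append(np.inf)
        assert np.median(errs) < 0.10


class TestPercentLipidMixing:
    def test_zero_and_full_mixing(self):
        times = np.linspace(0.5, 15, 100)
        s, b, t = _traces(times, np.full(100, 100.0), np.full(100, 100.0), np.full(100, 400.0))
        assert bk.percent_lipid_mixing(s, b, t).percent_mixing == pytest.approx(0.0)
        s2, _, _ = _traces(times, np.full(100, 600.0), np.full(100, 100.0), np.full(100, 400.0))
        res = bk.percent_lipid_mixing(s2, b, bk.FluorescenceTrace(times, np.full(100, 600.0), "triton"),
                                      correction_factor=1.0)
        assert res.percent_mixing == pytest.approx(100.0)

    def test_derived_midpoint_with_correction(self):
        """I0=100, observed Imax=400, It=350: corrected Imax=600 so mixing is 50 %."""
        times = np.linspace(0.5, 15, 100)
        s, b, t = _traces(times, np.full(100, 350.0), np.full(100, 100.0), np.full(100, 400.0))
        res = bk.percent_lipid_mixing(s, b, t, correction_factor=1.5)
        assert res.percent_mixing == pytest.approx(50.0)

    def test_degenerate_corrected_reference(self):
        times = np.linspace(0.5, 15, 100)
        s, b, t = _traces(times, np.full(100, 350.0), np.full(100, 600.0), np.full(100, 100.0))
        with pytest.raises(DegenerateReferenceError):
            bk.percent_lipid_mixing(s, b, t)

    @pytest.mark.parametrize("f_max", [0.0, 0.5, 1.0])
    def test_generator_round_trip(self, f_max):
        traces = bk.gen_mixing_traces(f_max, I0_level=100.0, Imax_obs_level=400.0)
        res = bk.percent_lipid_mixing(*traces)
        assert res.percent_mixing == pytest.approx(100.0 * f_max, abs=1e-9)

    def test_fmax_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bk.gen_mixing_traces(1.2)
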