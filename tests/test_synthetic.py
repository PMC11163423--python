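"""Generator contracts: exact inverses at zero noise, determinism, bookkeeping."""

import numpy as np
import pytest

import bilayerkit as bk
from bilayerkit.errors import ValidationError
from bilayerkit.nmr import pake_doublet_cdf


class TestLeakageGenerator:
    def test_half_plateau_at_tc(self):
        spec = bk.LeakageTraceSpec(a0=50.0, k=0.2, tc=10.0, t_end=40.0)
        series = bk.normalize_leakage(*bk.gen_leakage_traces(spec))
        assert np.interp(10.0, series.index, series.values) == pytest.approx(25.0, abs=1e-9)

    def test_plateau_reached_at_long_times(self):
        spec = bk.LeakageTraceSpec(a0=99.1, k=0.52, tc=0.87, t_end=200.0)
        series = bk.normalize_leakage(*bk.gen_leakage_traces(spec))
        assert series.iloc[-1] == pytest.approx(99.1, abs=1e-6)

    def test_zero_leakage_sample_equals_baseline(self):
        spec = bk.LeakageTraceSpec(a0=0.0, k=0.2, tc=10.0, t_end=40.0)
        sample, baseline, _ = bk.gen_leakage_traces(spec)
        assert np.array_equal(sample.intensities, baseline.intensities)

    def test_normalization_reproduces_sigmoid_exactly(self):
        spec = bk.LeakageTraceSpec(a0=73.0, k=0.35, tc=6.0, t_end=60.0)
        sample, baseline, triton = bk.gen_leakage_traces(spec)
        series = bk.normalize_leakage(sample, baseline, triton)
        expect = bk.sigmoid_leakage(series.index.values, 73.0, 0.35, 6.0)
        assert np.allclose(series.values, expect, atol=1e-12)

    def test_time_axes_shared_and_start_at_dead_time(self):
        spec = bk.LeakageTraceSpec(a0=50.0, k=0.2, tc=10.0)
        sample, baseline, triton = bk.gen_leakage_traces(spec)
        assert sample.times[0] == pytest.approx(0.5)
        assert np.array_equal(sample.times, baseline.times)
        assert np.array_equal(sample.times, triton.times)

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValidationError, match="a0"):
            bk.LeakageTraceSpec(a0=150.0, k=0.2, tc=10.0)
        with pytest.raises(ValidationError, match="Imax"):
            bk.LeakageTraceSpec(a0=50.0, k=0.2, tc=10.0, I0_level=100, Imax_level=90)

    def test_seeded_determinism(self):
        spec = bk.LeakageTraceSpec(a0=50.0, k=0.2, tc=10.0, noise_sd=5.0, seed=7)
        a = bk.gen_leakage_traces(spec)[0].intensities
        b = bk.gen_leakage_traces(spec)[0].intensities
        assert np.array_equal(a, b)


class TestPakeGenerator:
    def test_integral_equals_deuteron_count(self, plateau_decay_spectrum):
        spec, spectrum = plateau_decay_spectrum
        assert spectrum.integral() == pytest.approx(spec.profile.total_deuterons, rel=1e-6)

    def test_edge_singularities_at_three_quarters_chi_s(self, single_doublet_spectrum):
        """90-degree edges of a |S|=0.2 doublet sit 25.05 kHz apart (0.75*167*0.2)."""
        spec, spectrum = single_doublet_spectrum
        half = spectrum.axis > 0
        peak_pos = spectrum.axis[half][np.argmax(spectrum.intensity[half])]
        # broadening pulls the maximum slightly inside the singular edge
        tol = 2 * spec.broadening + 3 * spectrum.step
        assert 2 * peak_pos == pytest.approx(25.05, abs=tol)

    def test_matches_closed_form_pake_density(self, single_doublet_spectrum):
        """theta-grid powder sum agrees with the analytic doublet CDF."""
        spec, spectrum = single_doublet_spectrum
        d = 0.75 * spec.chi_q * 0.2
        step = spectrum.step
        edges = np.concatenate([spectrum.axis - step / 2, [spectrum.axis[-1] + step / 2]])
        mass = np.diff(pake_doublet_cdf(edges, d))
        exact = 2.0 * mass / step  # two deuterons
        kern_width = spec.broadening
        # compare cumulative distributions (robust to broadening near edges)
        cum_gen = np.cumsum(spectrum.intensity) * step
        cum_exact = np.cumsum(exact) * step
        assert np.max(np.abs(cum_gen - cum_exact)) < 0.05 * cum_exact[-1] + 10 * kern_width * 0.01

    def test_isotropic_profile_gives_central_line(self):
        profile = bk.OrderProfile([2, 3, 4], [0.0, 0.0, 0.0])
        spec = bk.PakeSpecInput(profile=profile, broadening=0.5, spectral_width=50.0)
        spectrum = bk.gen_pake_spectrum(spec)
        assert abs(spectrum.axis[np.argmax(spectrum.intensity)]) < spectrum.step
        # half the mass within a few broadening widths of zero
        mask = np.abs(spectrum.axis) < 5 * spec.broadening
        assert np.trapezoid(spectrum.intensity[mask], spectrum.axis[mask]) > 0.5 * spectrum.integral()

    def test_two_doublets_equal_integrals(self):
        profile = bk.OrderProfile([2, 3], [0.2, 0.1], deuteron_weights=[2.0, 2.0])
        spec = bk.PakeSpecInput(profile=profile, broadening=0.2, spectral_width=80.0)
        spectrum = bk.gen_pake_spectrum(spec)
        # split total mass at the inner doublet's parallel edge (0.75*167*0.1 kHz)
        cut = 0.75 * spec.chi_q * 0.1
        inner = np.abs(spectrum.axis) <= cut
        m_in = np.trapezoid(spectrum.intensity[inner], spectrum.axis[inner])
        m_tot = spectrum.integral()
        # inner region holds all of the |S|=0.1 doublet plus the inner flank
        # of the |S|=0.2 doublet (analytically 2*(cdf(cut)-cdf(-cut)) deuterons)
        d_outer = 0.75 * spec.chi_q * 0.2
        expect_outer_in = 2.0 * (pake_doublet_cdf(cut, d_outer) - pake_doublet_cdf(-cut, d_outer))
        assert m_tot == pytest.approx(4.0, rel=1e-6)
        assert m_in == pytest.approx(2.0 + expect_outer_in, abs=0.2)

    def test_narrow_spectral_width_rejected(self):
        profile = bk.OrderProfile([2], [0.4], deuteron_weights=[2.0])
        with pytest.raises(ValidationError, match="spectral_width"):
            bk.gen_pake_spectrum(bk.PakeSpecInput(profile=profile, spectral_width=60.0))

    def test_spectrum_symmetric(self, plateau_decay_spectrum):
        _, spectrum = plateau_decay_spectrum
        assert np.allclose(spectrum.intensity, spectrum.intensity[::-1])


class TestCSAGenerator:
    def test_zero_anisotropy_single_line(self):
        spectrum = bk.gen_csa_spectrum(bk.CSASpecInput(delta_sigma=0.0, sigma_iso=5.0))
        assert spectrum.axis[np.argmax(spectrum.intensity)] == pytest.approx(5.0, abs=2 * spectrum.step)

    def test_unit_integral_and_width(self):
        """A nearly unbroadened pattern spans |delta_sigma| on the ppm axis."""
        spec = bk.CSASpecInput(delta_sigma=45.9, sigma_iso=0.0, broadening=0.1)
        spectrum = bk.gen_csa_spectrum(spec)
        assert spectrum.integral() == pytest.approx(1.0, rel=1e-9)
        # support: from sigma_iso - ds/3 (peak) to sigma_iso + 2ds/3 (shoulder)
        above = spectrum.axis[spectrum.intensity > 0.05 * np.max(spectrum.intensity)]
        assert above[0] == pytest.approx(-45.9 / 3.0, abs=1.0)
        assert above[-1] == pytest.approx(2.0 * 45.9 / 3.0, abs=1.0)

    def test_round_trip_via_estimate(self):
        spectrum = bk.gen_csa_spectrum(bk.CSASpecInput(delta_sigma=30.0, sigma_iso=0.0, broadening=1.0))
        result = bk.estimate_csa(spectrum)
        assert result.delta_sigma == pytest.approx(30.0, abs=0.5)


class TestIsothermGenerator:
    def test_zero_pressure_above_liftoff_then_monotone_rise(self):
        spec = bk.IsothermModelSpec(lift_off_area=111.0)
        iso = bk.gen_isotherm(spec)
        assert np.all(iso.pressure[iso.area > 111.0] == 0.0)
        below = iso.pressure[iso.area < 111.0]
        assert np.all(np.diff(below) > 0)
        assert iso.max_pressure == pytest.approx(spec.collapse_pressure)

    def test_mixture_area_additivity_exact(self, component_isotherms):
        iso1, iso2 = component_isotherms
        chi = bk.MixtureComposition(("a", "b"), [0.7, 0.3])
        grid = np.linspace(0.0, 40.0, 200)
        excess = lambda p: 2.0 * np.ones_like(p)
        mix = bk.gen_mixture_isotherm(iso1, iso2, chi, excess_area_fn=excess, pressure_grid=grid)
        a1 = bk.area_at_pressure(iso1, grid)
        a2 = bk.area_at_pressure(iso2, grid)
        a_mix = bk.area_at_pressure(mix, grid)
        assert np.allclose(a_mix, 0.7 * a1 + 0.3 * a2 + 2.0, atol=1e-9)

    def test_non_descending_grid_rejected(self):
        with pytest.raises(ValidationError, match="area_grid"):
            bk.IsothermModelSpec(lift_off_area=100.0, area_grid=np.array([50.0, 60.0, 40.0]))

    def test_seeded_determinism(self):
        spec = bk.IsothermModelSpec(lift_off_area=111.0, noise_sd=0.1, seed=3)
        a = bk.gen_isotherm(spec).pressure
        b = bk.gen_isotherm(spec).pressure
        assert np.array_equal(a, b)
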