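"""Seeded forward models for every input class the analyses consume.

Each generator keeps its ground-truth parameters in the spec object so
analysis routines can be tested by parameter recovery: run the generator
noiselessly, run the inverse analysis, and compare against truth.

Conventions shared with the analysis modules (see constants.py):

* The 90-degree-edge splitting of a Pake doublet is
  (3/4) * chi_q * |S_CD|.
* An axially symmetric CSA pattern spans exactly |delta_sigma| on the
  ppm axis, with the 0-degree shoulder at sigma_iso + (2/3) delta_sigma.
* Leakage kinetics follow a0 / (1 + exp(-(t - tc) * k)); traces start at
  the 30 s instrument dead time and never earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constants import SPLITTING_PREFACTOR
from .datatypes import (
    FluorescenceTrace,
    Isotherm,
    MixtureComposition,
    OrderProfile,
    PowderSpectrum,
)
from .errors import ValidationError

#: Instrument dead time between mixing and the first recorded point, minutes.
DEAD_TIME_MIN = 30.0 / 60.0


# ---------------------------------------------------------------------------
# Spec objects
# ---------------------------------------------------------------------------

@dataclass
class LeakageTraceSpec:
    """Ground truth for a calcein-leakage fluorescence experiment.

    a0 (plateau %), k (1/min) and tc (min) parametrize the sigmoid;
    I0_level and Imax_level set the baseline and Triton-lysed reference
    intensities in arbitrary units.
    """

    a0: float
    k: float
    tc: float
    t_start: float = 30.0  # seconds (dead time)
    t_end: float = 40.0    # minutes
    dt: float = 0.1        # minutes
    I0_level: float = 100.0
    Imax_level: float = 1100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.a0 <= 100.0):
            raise ValidationError(f"a0: {self.a0} outside [0, 100]")
        if self.k < 0:
            raise ValidationError(f"k: {self.k} must be >= 0")
        if self.Imax_level <= self.I0_level:
            raise ValidationError("Imax_level: must exceed I0_level")
        if self.dt <= 0:
            raise ValidationError(f"dt: {self.dt} must be > 0")
        if self.t_end <= self.t_start / 60.0:
            raise ValidationError("t_end: must exceed the dead time")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd: {self.noise_sd} must be >= 0")


@dataclass
class PakeSpecInput:
    """Forward-model inputs for a static 2H powder spectrum."""

    profile: OrderProfile
    chi_q: float = 167.0          # kHz
    broadening: float = 0.5       # Lorentzian half-width, kHz
    n_points: int = 2048
    spectral_width: float = 250.0  # kHz
    n_theta: int = 2000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chi_q <= 0:
            raise ValidationError(f"chi_q: {self.chi_q} must be > 0")
        if self.n_points < 256:
            raise ValidationError(f"n_points: {self.n_points} must be >= 256")
        if self.n_theta < 500:
            raise ValidationError(f"n_theta: {self.n_theta} must be >= 500")
        if self.profile.n_carbons == 0:
            raise ValidationError("profile: must be non-empty")
        if self.broadening < 0:
            raise ValidationError(f"broadening: {self.broadening} must be >= 0")


@dataclass
class CSASpecInput:
    """Forward-model inputs for an axially symmetric 31P CSA powder pattern."""

    delta_sigma: float            # ppm (reported as a magnitude)
    sigma_iso: float = 0.0        # ppm
    broadening: float = 1.0       # Lorentzian half-width, ppm
    n_points: int = 1024
    n_theta: int = 2000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 256:
            raise ValidationError(f"n_points: {self.n_points} must be >= 256")
        if self.n_theta < 500:
            raise ValidationError(f"n_theta: {self.n_theta} must be >= 500")
        if self.broadening < 0:
            raise ValidationError(f"broadening: {self.broadening} must be >= 0")


@dataclass
class IsothermModelSpec:
    """A smooth LE->LC compression isotherm with a sharp lift-off.

    pi(A) = 0 for A above lift_off_area; below it the pressure rises as a
    normalized (x + steepness * x^3) law in x = (A0 - A)/(A0 - A_end),
    reaching collapse_pressure at the smallest grid area.  steepness = 0
    gives a linear rise; larger values bend the curve the way an LE->LC
    transition does, without a coexistence plateau.
    """

    lift_off_area: float            # A^2 / molecule
    collapse_pressure: float = 45.0  # mN/m
    steepness: float = 3.0
    area_grid: np.ndarray | None = None  # descending, A^2/molecule
    composition: MixtureComposition | None = None
    noise_sd: float = 0.0            # mN/m
    seed: int = 0

    def __post_init__(self):
        if self.lift_off_area <= 0:
            raise ValidationError(f"lift_off_area: {self.lift_off_area} must be > 0")
        if self.collapse_pressure <= 0:
            raise ValidationError(f"collapse_pressure: {self.collapse_pressure} must be > 0")
        if self.steepness < 0:
            raise ValidationError(f"steepness: {self.steepness} must be >= 0")
        if self.area_grid is None:
            self.area_grid = np.arange(1.25 * self.lift_off_area, 0.35 * self.lift_off_area, -0.1)
        self.area_grid = np.asarray(self.area_grid, dtype=float)
        if np.any(np.diff(self.area_grid) >= 0):
            raise ValidationError("area_grid: must be strictly decreasing")


# ---------------------------------------------------------------------------
# Fluorescence generators
# ---------------------------------------------------------------------------

def sigmoid_leakage(t: np.ndarray, a0: float, k: float, tc: float) -> np.ndarray:
    """Percent dye leakage a0 / (1 + exp(-(t - tc) * k))."""
    return a0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - tc) * k))


def gen_leakage_traces(spec: LeakageTraceSpec):
    """Simulate the three channels of a calcein leakage experiment.

    Returns (sample, baseline, triton) FluorescenceTrace objects sharing
    one time axis that starts at the dead time.  Normalizing them with
    the leakage equation reproduces the generating sigmoid exactly when
    noise_sd = 0.
    """
    t0 = spec.t_start / 60.0
    times = np.arange(0.0, spec.t_end - t0 + spec.dt / 2, spec.dt) + t0
    leak = sigmoid_leakage(times, spec.a0, spec.k, spec.tc)
    rng = np.random.default_rng(spec.seed)
    span = spec.Imax_level - spec.I0_level
    i0 = np.full_like(times, spec.I0_level)
    imax = np.full_like(times, spec.Imax_level)
    it = spec.I0_level + leak / 100.0 * span
    if spec.noise_sd > 0:
        it = it + rng.normal(0.0, spec.noise_sd, times.size)
        i0 = i0 + rng.normal(0.0, spec.noise_sd, times.size)
        imax = imax + rng.normal(0.0, spec.noise_sd, times.size)
    meta = {"truth": {"a0": spec.a0, "k": spec.k, "tc": spec.tc}}
    return (
        FluorescenceTrace(times, it, "sample", dict(meta)),
        FluorescenceTrace(times, i0, "baseline", dict(meta)),
        FluorescenceTrace(times, imax, "triton", dict(meta)),
    )


def gen_mixing_traces(
    f_max: float,
    I0_level: float = 100.0,
    Imax_obs_level: float = 400.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    correction_factor: float = 1.5,
    read_time: float = 10.0,
    t_end: float = 15.0,
    dt: float = 0.1,
):
    """Simulate an NBD dequenching (probe dilution) experiment.

    The sample channel saturates so that at ``read_time`` the mixing
    equation, with ``correction_factor`` applied to the observed Triton
    intensity, returns exactly 100 * f_max on noiseless output.
    """
    if not (0.0 <= f_max <= 1.0):
        raise ValidationError(f"f_max: {f_max} outside [0, 1]")
    if Imax_obs_level <= 0:
        raise ValidationError(f"Imax_obs_level: {Imax_obs_level} must be > 0")
    times = np.arange(0.0, t_end - DEAD_TIME_MIN + dt / 2, dt) + DEAD_TIME_MIN
    # Smooth saturation pinned to f_max exactly at the read point.
    f = f_max * (1.0 - np.exp(-3.0 * times / read_time)) / (1.0 - np.exp(-3.0))
    f = np.minimum(f, f_max)
    imax_corr = correction_factor * Imax_obs_level
    it = I0_level + f * (imax_corr - I0_level)
    i0 = np.full_like(times, I0_level)
    imax = np.full_like(times, Imax_obs_level)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        it = it + rng.normal(0.0, noise_sd, times.size)
        i0 = i0 + rng.normal(0.0, noise_sd, times.size)
        imax = imax + rng.normal(0.0, noise_sd, times.size)
    meta = {"truth": {"f_max": f_max, "correction_factor": correction_factor}}
    return (
        FluorescenceTrace(times, it, "sample", dict(meta)),
        FluorescenceTrace(times, i0, "baseline", dict(meta)),
        FluorescenceTrace(times, imax, "triton", dict(meta)),
    )


# ---------------------------------------------------------------------------
# NMR powder-pattern generators
# ---------------------------------------------------------------------------

def plateau_decay_profile(
    n_carbons: int = 15,
    plateau_carbons: int = 6,
    methyl_ratio: float = 0.35,
    mean: float | None = None,
    plateau_s: float = 0.2,
) -> OrderProfile:
    """Template |S_CD| profile: an order plateau decaying toward the methyl.

    The first ``plateau_carbons`` positions sit at a constant plateau;
    the rest fall along a half-cosine to ``methyl_ratio`` times the
    plateau at the terminal methyl -- the canonical shape of a fluid
    phospholipid sn-1 chain.  If ``mean`` is given the whole profile is
    scaled so its unweighted mean equals it (the scaled plateau must
    stay within the physical bound |S_CD| <= 0.5).
    """
    if n_carbons < 3:
        raise ValidationError(f"n_carbons: {n_carbons} must be >= 3")
    if not (0 < plateau_carbons < n_carbons):
        raise ValidationError("plateau_carbons: must be in (0, n_carbons)")
    rel = np.ones(n_carbons)
    n_decay = n_carbons - plateau_carbons
    x = np.arange(1, n_decay + 1) / n_decay
    rel[plateau_carbons:] = methyl_ratio + (1.0 - methyl_ratio) * 0.5 * (1.0 + np.cos(np.pi * x))
    s = plateau_s * rel
    if mean is not None:
        s = s * (mean / float(np.mean(s)))
    carbons = np.arange(2, n_carbons + 2)
    return OrderProfile(carbons, s)


def _lorentzian_kernel(step: float, half_width: float, n: int) -> np.ndarray:
    """Unit-area discrete Lorentzian, odd length fitting the axis."""
    half_n = (n - 1) // 2
    x = np.arange(-half_n, half_n + 1) * step
    kern = half_width / np.pi / (x * x + half_width * half_width)
    return kern / np.sum(kern)


def _bin_powder(freqs: np.ndarray, weights: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Histogram orientation frequencies onto a uniform axis.

    Weights are split linearly between the two neighbouring bins so the
    pattern is smooth at the n_theta resolution.
    """
    step = axis[1] - axis[0]
    pos = (freqs - axis[0]) / step
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    out = np.zeros(axis.size)
    ok = (lo >= 0) & (lo < axis.size - 1)
    np.add.at(out, lo[ok], weights[ok] * (1.0 - frac[ok]))
    np.add.at(out, lo[ok] + 1, weights[ok] * frac[ok])
    return out


def gen_pake_spectrum(spec: PakeSpecInput) -> PowderSpectrum:
    """Deuteron-weighted superposition of Pake doublets from an order profile.

    Each carbon i contributes a powder-averaged doublet with transition
    frequencies +/- (delta_i / 2) * (3 cos^2 theta - 1) where
    delta_i = (3/4) * chi_q * |S_CD(i)| is the 90-degree-edge splitting.
    The powder average uses a uniform theta grid with sin(theta) weights.
    The total integral equals the deuteron count (CD2 = 2, CD3 = 3).
    """
    splittings = SPLITTING_PREFACTOR * spec.chi_q * spec.profile.s_cd
    if spec.spectral_width < 2.0 * np.max(splittings, initial=0.0):
        raise ValidationError(
            "spectral_width: smaller than twice the largest splitting "
            f"({np.max(splittings):.2f} kHz)"
        )
    axis = np.linspace(-spec.spectral_width / 2, spec.spectral_width / 2, spec.n_points)
    theta = (np.arange(spec.n_theta) + 0.5) * (np.pi / 2) / spec.n_theta
    w_theta = np.sin(theta)
    angular = (3.0 * np.cos(theta) ** 2 - 1.0) / 2.0
    intensity = np.zeros(spec.n_points)
    for d, w_c in zip(splittings, spec.profile.deuteron_weights):
        nu = d * angular  # one transition; the mirror gives the other
        intensity += w_c * _bin_powder(nu, w_theta, axis)
        intensity += w_c * _bin_powder(-nu, w_theta, axis)
    if spec.broadening > 0:
        step = axis[1] - axis[0]
        kern = _lorentzian_kernel(step, spec.broadening, spec.n_points)
        intensity = np.convolve(intensity, kern, mode="same")
    # Symmetrize (binning is mirror-symmetric only up to grid parity).
    intensity = 0.5 * (intensity + intensity[::-1])
    integral = np.trapezoid(intensity, axis)
    intensity *= spec.profile.total_deuterons / integral
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.abs(intensity + rng.normal(0.0, spec.noise_sd, intensity.size))
    return PowderSpectrum(axis, intensity, nucleus="2H")


def gen_csa_spectrum(spec: CSASpecInput) -> PowderSpectrum:
    """Axially symmetric CSA powder pattern with Lorentzian broadening.

    The pattern spans |delta_sigma| on the ppm axis: the 90-degree edge
    (the peak) sits at sigma_iso - delta_sigma/3 and the 0-degree
    shoulder at sigma_iso + 2 delta_sigma/3.  Unit integral.
    """
    ds = spec.delta_sigma
    pad = max(3.0 * spec.broadening, 0.35 * abs(ds), 2.0)
    lo = spec.sigma_iso - abs(ds) / 3.0 - pad
    hi = spec.sigma_iso + 2.0 * abs(ds) / 3.0 + pad
    if ds < 0:
        lo, hi = spec.sigma_iso - 2.0 * abs(ds) / 3.0 - pad, spec.sigma_iso + abs(ds) / 3.0 + pad
    axis = np.linspace(lo, hi, spec.n_points)
    theta = (np.arange(spec.n_theta) + 0.5) * (np.pi / 2) / spec.n_theta
    w_theta = np.sin(theta)
    sigma = spec.sigma_iso + ds * (3.0 * np.cos(theta) ** 2 - 1.0) / 3.0
    intensity = _bin_powder(sigma, w_theta, axis)
    if spec.broadening > 0:
        step = axis[1] - axis[0]
        kern = _lorentzian_kernel(step, spec.broadening, spec.n_points)
        intensity = np.convolve(intensity, kern, mode="same")
    intensity /= np.trapezoid(intensity, axis)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.abs(intensity + rng.normal(0.0, spec.noise_sd, intensity.size))
    return PowderSpectrum(axis, intensity, nucleus="31P")


# ---------------------------------------------------------------------------
# Isotherm generators
# ---------------------------------------------------------------------------

def isotherm_pressure(
    area: np.ndarray,
    lift_off_area: float,
    collapse_pressure: float,
    steepness: float,
    area_end: float | None = None,
) -> np.ndarray:
    """Analytic pressure law of the synthetic isotherm (noise-free).

    Exposed separately so derivative-based analyses can be checked
    against the closed form.
    """
    area = np.asarray(area, dtype=float)
    if area_end is None:
        area_end = float(np.min(area))
    x = np.clip((lift_off_area - area) / (lift_off_area - area_end), 0.0, None)
    return collapse_pressure * (x + steepness * x**3) / (1.0 + steepness)


def gen_isotherm(spec: IsothermModelSpec) -> Isotherm:
    """Generate a smooth LE->LC isotherm on the spec's descending area grid."""
    pressure = isotherm_pressure(
        spec.area_grid, spec.lift_off_area, spec.collapse_pressure, spec.steepness
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pressure = pressure + rng.normal(0.0, spec.noise_sd, pressure.size)
        pressure = np.maximum(pressure, -0.49)
    return Isotherm(spec.area_grid.copy(), pressure, composition=spec.composition)


def gen_mixture_isotherm(
    iso_1: Isotherm,
    iso_2: Isotherm,
    composition: MixtureComposition,
    excess_area_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    pressure_grid: np.ndarray | None = None,
) -> Isotherm:
    """Construct a binary-mixture isotherm by area additivity.

    A12(pi) = chi1 * A1(pi) + chi2 * A2(pi) + A_excess(pi), evaluated on
    an ascending pressure grid, so the excess Gibbs free energy of the
    result is known exactly from ``excess_area_fn``.
    """
    from .monolayer import area_at_pressure  # local import avoids a cycle

    if composition.mole_fractions.size != 2:
        raise ValidationError("composition: mixture construction requires a binary system")
    if pressure_grid is None:
        top = min(iso_1.max_pressure, iso_2.max_pressure)
        pressure_grid = np.linspace(0.0, top, 600)
    pressure_grid = np.asarray(pressure_grid, dtype=float)
    chi1, chi2 = composition.mole_fractions
    a1 = area_at_pressure(iso_1, pressure_grid)
    a2 = area_at_pressure(iso_2, pressure_grid)
    a12 = chi1 * a1 + chi2 * a2
    if excess_area_fn is not None:
        a12 = a12 + np.asarray(excess_area_fn(pressure_grid), dtype=float)
    # Compression order: areas descending, pressures ascending.
    order = np.argsort(-a12)
    area = a12[order]
    pres = pressure_grid[order]
    keep = np.concatenate([[True], np.diff(area) < 0])
    return Isotherm(area[keep], pres[keep], composition=composition)
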