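"""Langmuir monolayer thermodynamics from pressure-area isotherms.

Implements the standard quantities read off a compression isotherm
pi(A):

* composition bookkeeping (mol % of an additive, spread-film mean
  molecular area),
* the static in-plane elasticity (compressional modulus)
  Cs^-1 = -A (dpi/dA)_T,
* the excess Gibbs free energy of mixing of a binary film,
  dG_exc = int_{pi_lo}^{pi_hi} (A12 - chi1 A1 - chi2 A2) dpi,
* the lift-off area, the largest mean molecular area at which the
  surface pressure first rises above its large-area baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .constants import AREA_PRESSURE_TO_J_PER_MOL
from .datatypes import GibbsExcessResult, Isotherm, MixtureComposition
from .errors import CoverageError, NoLiftOffError, ValidationError


def molpercent_il(conc_il: float, conc_lipid: float) -> float:
    """Mol % of ionic liquid in an IL/lipid mixture: 100 [IL]/([IL]+[Lipid])."""
    if conc_il < 0 or conc_lipid < 0:
        raise ValidationError("concentrations must be >= 0")
    total = conc_il + conc_lipid
    if total == 0:
        raise ValidationError("conc_il and conc_lipid cannot both be zero")
    return 100.0 * conc_il / total


def mma_axis(
    trough_area: float,
    spread_volume: float,
    stock_conc: float,
    mean_molar_mass: float,
) -> tuple[float, float]:
    """Molecule count and starting mean molecular area of a spread film.

    trough_area in cm^2, spread_volume in uL, stock_conc in mg/mL,
    mean_molar_mass in g/mol.  Returns (N_molecules, MMA in A^2/molecule).
    """
    for name, v in [("trough_area", trough_area), ("spread_volume", spread_volume),
                    ("stock_conc", stock_conc), ("mean_molar_mass", mean_molar_mass)]:
        if v <= 0:
            raise ValidationError(f"{name}: must be > 0")
    mass_g = spread_volume * 1e-3 * stock_conc * 1e-3  # uL * mg/mL -> g
    n_molecules = mass_g / mean_molar_mass * Avogadro
    if n_molecules < 1:
        raise ValidationError("mean_molar_mass: fewer than one molecule spread")
    mma = trough_area * 1e16 / n_molecules  # cm^2 -> A^2
    return float(n_molecules), float(mma)


def static_elasticity(iso: Isotherm, smoothing_window: int = 11) -> np.ndarray:
    """Compressional modulus Cs^-1(A) = -A (dpi/dA)_T, in mN/m.

    The derivative is a local-quadratic (Savitzky-Golay) estimate with
    one-sided polynomial stencils at the endpoints; for non-uniform area
    grids a windowed polynomial fit is used instead.
    """
    if len(iso) < 7:
        raise ValidationError("static_elasticity requires >= 7 points")
    if smoothing_window > len(iso):
        raise ValidationError("smoothing_window larger than the isotherm")
    if smoothing_window % 2 == 0:
        smoothing_window += 1
    a, p = iso.area, iso.pressure
    steps = np.diff(a)
    if np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        dpi_da = savgol_filter(p, smoothing_window, polyorder=2, deriv=1,
                               delta=steps[0], mode="interp")
    else:
        half = smoothing_window // 2
        dpi_da = np.empty_like(p)
        for i in range(p.size):
            lo, hi = max(0, i - half), min(p.size, i + half + 1)
            coeff = np.polyfit(a[lo:hi] - a[i], p[lo:hi], 2)
            dpi_da[i] = coeff[-2]
    return -a * dpi_da


def area_at_pressure(iso: Isotherm, pressures: np.ndarray) -> np.ndarray:
    """Interpolate A(pi) along the compression branch.

    pi is made monotone non-decreasing along compression by isotonic
    (running-maximum) projection before inversion; where a pressure is
    held over an interval of areas (e.g. the zero-pressure region before
    lift-off) the smallest area attained at that pressure is used, so
    A(0) is the lift-off area.
    """
    pressures = np.asarray(pressures, dtype=float)
    p = iso.pressure.copy()
    p_mono = np.maximum.accumulate(p)
    if not np.array_equal(p_mono, p):
        warnings.warn("non-monotone pressure segments projected to monotone", stacklevel=2)
    if np.any(pressures > p_mono[-1] + 1e-12):
        raise CoverageError(
            f"isotherm reaches only {p_mono[-1]:.3f} mN/m, "
            f"requested up to {np.max(pressures):.3f}"
        )
    # Keep, for each pressure level, the last (smallest-area) occurrence.
    keep = np.concatenate([p_mono[:-1] < p_mono[1:], [True]])
    return np.interp(pressures, p_mono[keep], iso.area[keep])


def gibbs_excess(
    iso_mix: Isotherm,
    iso_1: Isotherm,
    iso_2: Isotherm,
    chi: MixtureComposition,
    pi_lo: float = 0.0,
    pi_hi: float = 30.0,
    n_grid: int = 601,
) -> GibbsExcessResult:
    """Excess Gibbs free energy of mixing of a binary monolayer, J/mol.

    dG_exc = int (A12 - chi1 A1 - chi2 A2) dpi over [pi_lo, pi_hi],
    areas interpolated onto a common pressure grid, trapezoidal rule,
    converted with 1 (A^2/molecule)(mN/m) = 6.022e-3 kJ/mol.
    """
    if chi.mole_fractions.size != 2:
        raise ValidationError("chi: gibbs_excess is defined for a binary system")
    if pi_hi <= pi_lo:
        raise ValidationError("pressure range: pi_hi must exceed pi_lo")
    grid = np.linspace(pi_lo, pi_hi, n_grid)
    a12 = area_at_pressure(iso_mix, grid)
    a1 = area_at_pressure(iso_1, grid)
    a2 = area_at_pressure(iso_2, grid)
    chi1, chi2 = chi.mole_fractions
    excess = a12 - chi1 * a1 - chi2 * a2
    dg = float(np.trapezoid(excess, grid)) * AREA_PRESSURE_TO_J_PER_MOL
    return GibbsExcessResult(delta_G_exc=dg, pressure_range=(pi_lo, pi_hi),
                             A1=a1, A2=a2, A12=a12)


def liftoff_area(iso: Isotherm, threshold: float = 0.5, refine: bool = True) -> float:
    """Lift-off area: onset of surface pressure on compression, A^2/molecule.

    The baseline is the median pressure over the largest-area decile of
    the record.  The detector locates the largest area at which the
    (lightly smoothed) pressure first exceeds baseline + threshold.
    When ``refine`` is True (default) the onset is sharpened by a
    segmented (hinge) fit of the flat region plus the early rise arc,
    which places the lift-off to within one grid step on noiseless data
    and to within a few grid steps under pressure noise of a fifth of
    the threshold; refine=False returns the raw crossing area.
    """
    a, p = iso.area, iso.pressure
    n10 = max(len(iso) // 10, 2)
    baseline = float(np.median(p[:n10]))
    level = baseline + threshold
    if len(iso) >= 15:
        p_smooth = savgol_filter(p, 15, polyorder=2, mode="interp")
    else:
        p_smooth = p
    above = p_smooth > level
    if not np.any(above):
        raise NoLiftOffError(
            f"pressure never exceeds baseline ({baseline:.3f}) + threshold ({threshold:g}) mN/m"
        )
    i_cross = int(np.argmax(above))  # first crossing on compression
    if not refine:
        return float(a[i_cross])
    # Segmented (hinge) fit over the flat region and the early rise arc
    # (up to baseline + 4 * threshold): pi = b + c*(A0 - A) + q*(A0 - A)^2
    # past the kink.  The quadratic term absorbs the arc's curvature so
    # the kink position is unbiased for smooth onsets.
    arc_end = p_smooth > baseline + 4.0 * threshold
    i_end = int(np.argmax(arc_end)) if np.any(arc_end) else len(iso)
    i_end = max(i_end, min(i_cross + 4, len(iso)))
    a_fit, p_fit = a[:i_end], p[:i_end]

    arc = slice(i_cross, i_end)
    if i_end - i_cross >= 2:
        c0 = max(-np.polyfit(a[arc], p[arc], 1)[0], 1e-6)
    else:
        c0 = threshold

    def resid(x):
        b, c, q, a0 = x
        da = np.clip(a0 - a_fit, 0.0, None)
        return b + c * da + q * da * da - p_fit

    res = least_squares(resid, np.array([baseline, c0, 0.0, a[i_cross]]),
                        bounds=([-np.inf, 1e-9, -np.inf, a_fit[-1]],
                                [np.inf, np.inf, np.inf, a_fit[0]]))
    return float(res.x[3])
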