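"""Core data containers for fluorescence, NMR, and monolayer analyses.

All containers are frozen-ish dataclasses holding numpy arrays plus the
metadata the analyses need (channel labels, nucleus, composition).
Validation happens at construction; downstream code can assume the
invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name}: expected a 1-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: contains non-finite values")
    return arr


@dataclass
class FluorescenceTrace:
    """A time-indexed fluorescence intensity series.

    times are minutes and strictly increasing; channel identifies the
    role of the trace in the assay (sample / baseline / triton).
    """

    times: np.ndarray
    intensities: np.ndarray
    channel: str = "sample"
    meta: dict = field(default_factory=dict)

    _CHANNELS = ("sample", "baseline", "triton")

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.times.size != self.intensities.size:
            raise ValidationError(
                f"times/intensities length mismatch: {self.times.size} != {self.intensities.size}"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times: must be strictly increasing")
        if self.channel not in self._CHANNELS:
            raise ValidationError(f"channel: {self.channel!r} not in {self._CHANNELS}")

    def __len__(self) -> int:
        return self.times.size

    def value_at(self, t: float) -> float:
        """Linearly interpolated intensity at time t (minutes)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValidationError(
                f"times: t={t} outside trace span [{self.times[0]}, {self.times[-1]}]"
            )
        return float(np.interp(t, self.times, self.intensities))


@dataclass
class SigmoidFit:
    """Result of the sigmoidal leakage-kinetics fit.

    a0 is the plateau leakage (%), k the rate constant (1/min) and tc the
    half-leakage time (min).  converged=False marks a non-identifiable
    fit (flat trace / rise outside the sampled window); k and tc are then
    NaN, mirroring an 'N.D.' table entry, while a0 still reports the
    plateau.
    """

    a0: float
    k: float
    tc: float
    se_a0: float = float("nan")
    se_k: float = float("nan")
    se_tc: float = float("nan")
    converged: bool = True
    residual_rms: float = float("nan")

    def __post_init__(self):
        if self.converged:
            if not (0.0 <= self.a0 <= 110.0):
                raise ValidationError(f"a0: {self.a0} outside [0, 110]")
            if self.k < 0:
                raise ValidationError(f"k: {self.k} must be >= 0")


@dataclass
class MixingResult:
    """Percent lipid mixing at the read time of the probe-dilution assay."""

    percent_mixing: float
    correction_factor: float = 1.5
    read_time: float = 10.0

    def __post_init__(self):
        if self.correction_factor <= 0:
            raise ValidationError(f"correction_factor: {self.correction_factor} must be > 0")


@dataclass
class PowderSpectrum:
    """A powder line shape on a uniform axis.

    axis is frequency in kHz (centered at 0) for 2H or chemical shift in
    ppm for 31P; intensity is non-negative.
    """

    axis: np.ndarray
    intensity: np.ndarray
    nucleus: str = "2H"

    _NUCLEI = ("2H", "31P")

    def __post_init__(self):
        self.axis = _as_float_array(self.axis, "axis")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.axis.size != self.intensity.size:
            raise ValidationError("axis/intensity length mismatch")
        d = np.diff(self.axis)
        if self.axis.size < 2 or np.any(d <= 0):
            raise ValidationError("axis: must be increasing with >= 2 points")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("axis: must be uniformly spaced")
        if np.any(self.intensity < -1e-12 * max(1.0, float(np.max(np.abs(self.intensity))))):
            raise ValidationError("intensity: must be non-negative")
        if self.nucleus not in self._NUCLEI:
            raise ValidationError(f"nucleus: {self.nucleus!r} not in {self._NUCLEI}")

    @property
    def step(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.axis))


@dataclass
class DePakedSpectrum:
    """Oriented-sample subspectrum: intensity vs quadrupolar splitting (kHz >= 0)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.axis = _as_float_array(self.axis, "axis")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.axis.size != self.intensity.size:
            raise ValidationError("axis/intensity length mismatch")
        if np.any(self.axis < 0):
            raise ValidationError("axis: splittings must be >= 0")
        if np.any(self.intensity < 0):
            raise ValidationError("intensity: must be non-negative after regularization")

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.axis))


@dataclass
class OrderProfile:
    """|S_CD| per carbon along a perdeuterated sn-1 chain.

    carbons run from position 2 (next to the glycerol backbone) to the
    terminal methyl; interior carbons carry two deuterons (CD2), the
    terminal methyl three (CD3).
    """

    carbons: np.ndarray
    s_cd: np.ndarray
    deuteron_weights: np.ndarray | None = None

    def __post_init__(self):
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.s_cd = _as_float_array(self.s_cd, "s_cd")
        if self.carbons.size != self.s_cd.size:
            raise ValidationError("carbons/s_cd length mismatch")
        if self.carbons.size and np.any(np.diff(self.carbons) != 1):
            raise ValidationError("carbons: must be consecutive positions")
        if np.any(self.s_cd < 0) or np.any(self.s_cd > 0.5 + 1e-12):
            raise ValidationError("s_cd: |S_CD| must lie in [0, 0.5]")
        if self.deuteron_weights is None:
            w = np.full(self.carbons.size, 2.0)
            if w.size:
                w[-1] = 3.0  # terminal CD3
            self.deuteron_weights = w
        else:
            self.deuteron_weights = _as_float_array(self.deuteron_weights, "deuteron_weights")
            if self.deuteron_weights.size != self.carbons.size:
                raise ValidationError("deuteron_weights length mismatch")
            if np.any(self.deuteron_weights <= 0):
                raise ValidationError("deuteron_weights: must be positive")

    @property
    def n_carbons(self) -> int:
        return self.carbons.size

    @property
    def total_deuterons(self) -> float:
        return float(np.sum(self.deuteron_weights))


@dataclass
class ChainSummary:
    """Average order parameter and chain extent derived from a profile."""

    avg_S: float
    Lc_star: float
    chi_q: float

    def __post_init__(self):
        if not (0.0 <= self.avg_S <= 0.5):
            raise ValidationError(f"avg_S: {self.avg_S} outside [0, 0.5]")
        if self.Lc_star <= 0:
            raise ValidationError(f"Lc_star: {self.Lc_star} must be > 0")


@dataclass
class CSAResult:
    """Chemical shift anisotropy estimate from a 31P powder pattern."""

    delta_sigma: float
    sigma_iso: float
    fit_rms: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if not np.isfinite(self.delta_sigma):
            raise ValidationError("delta_sigma: must be finite")


@dataclass
class MixtureComposition:
    """Component labels and mole fractions of a (usually binary) mixture."""

    components: tuple
    mole_fractions: np.ndarray

    def __post_init__(self):
        self.components = tuple(self.components)
        self.mole_fractions = _as_float_array(self.mole_fractions, "mole_fractions")
        if len(self.components) != self.mole_fractions.size:
            raise ValidationError("components/mole_fractions length mismatch")
        if np.any(self.mole_fractions < 0):
            raise ValidationError("mole_fractions: must be >= 0")
        if abs(float(np.sum(self.mole_fractions)) - 1.0) > 1e-9:
            raise ValidationError("mole_fractions: must sum to 1")


@dataclass
class Isotherm:
    """A Langmuir pressure-area isotherm recorded on compression.

    area is the mean molecular area in A^2/molecule, strictly decreasing
    (compression order); pressure is surface pressure in mN/m.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 25.0
    composition: MixtureComposition | None = None

    def __post_init__(self):
        self.area = _as_float_array(self.area, "area")
        self.pressure = _as_float_array(self.pressure, "pressure")
        if self.area.size != self.pressure.size:
            raise ValidationError("area/pressure length mismatch")
        if np.any(np.diff(self.area) >= 0):
            raise ValidationError("area: must be strictly decreasing (compression order)")
        if np.any(self.pressure < -0.5):
            raise ValidationError("pressure: values below -0.5 mN/m")

    def __len__(self) -> int:
        return self.area.size

    @property
    def max_pressure(self) -> float:
        return float(np.max(self.pressure))


@dataclass
class GibbsExcessResult:
    """Excess Gibbs free energy of mixing integrated over a pressure range."""

    delta_G_exc: float
    pressure_range: tuple
    A1: np.ndarray | None = None
    A2: np.ndarray | None = None
    A12: np.ndarray | None = None
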