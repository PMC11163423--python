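"""Leakage and lipid-mixing fluorescence analysis.

The dye-leakage assay reports the percentage of encapsulated calcein
released from vesicles:

    % leakage(t) = 100 * (I_t - I_0,t) / (I_max,t - I_0,t)

where I_0,t is the baseline (no ionic liquid), I_t the sample and
I_max,t the Triton-lysed reference.  The time course is smoothed by
three-point averaging and fitted with the sigmoid

    % leakage(t) = a0 / (1 + exp(-(t - tc) * k))

yielding the plateau a0 (%), rate constant k (1/min) and half-leakage
time tc (min).  Lipid mixing from the NBD dequenching assay uses the
same normalization at a single read time, with the observed post-Triton
intensity multiplied by a correction factor (default 1.5) because
Triton X-100 suppresses NBD-PE fluorescence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lmfit import Model

from .datatypes import FluorescenceTrace, MixingResult, SigmoidFit
from .errors import AlignmentError, DegenerateReferenceError, ValidationError
from .synthetic import sigmoid_leakage

K_UPPER_BOUND = 50.0  # 1/min; rises faster than this are unresolvable at typical sampling
A0_UPPER_BOUND = 110.0  # % (allows modest normalization overshoot)


def _check_alignment(*traces: FluorescenceTrace) -> np.ndarray:
    ref = traces[0].times
    for tr in traces[1:]:
        if tr.times.size != ref.size or not np.allclose(tr.times, ref, rtol=0, atol=1e-9):
            raise AlignmentError("traces do not share an identical time axis")
    return ref


def normalize_leakage(
    sample: FluorescenceTrace,
    baseline: FluorescenceTrace,
    triton: FluorescenceTrace,
) -> pd.Series:
    """Pointwise percent dye leakage, indexed by time in minutes.

    Values are not clipped to [0, 100]: small negative excursions are
    informative for quality control and are reported as-is.
    """
    times = _check_alignment(sample, baseline, triton)
    denom = triton.intensities - baseline.intensities
    if np.any(denom <= 0):
        bad = times[denom <= 0][0]
        raise DegenerateReferenceError(
            f"I_max,t - I_0,t is non-positive at t = {bad:g} min"
        )
    leak = 100.0 * (sample.intensities - baseline.intensities) / denom
    return pd.Series(leak, index=pd.Index(times, name="time_min"), name="percent_leakage")


def smooth3(series: pd.Series) -> pd.Series:
    """Three-point centered moving average; one-sided two-point mean at the ends."""
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValidationError("smooth3 requires at least 3 points")
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    out[0] = (y[0] + y[1]) / 2.0
    out[-1] = (y[-2] + y[-1]) / 2.0
    return pd.Series(out, index=series.index, name=series.name)


def _sigmoid_model(t, a0, k, tc):
    return sigmoid_leakage(t, a0, k, tc)


def fit_sigmoid(
    leakage: pd.Series,
    smooth: bool = True,
    flat_rel_range: float = 0.02,
) -> SigmoidFit:
    """Fit the sigmoidal leakage model to a percent-leakage time series.

    By default the series is three-point smoothed before fitting,
    matching the assay's plotting convention; pass smooth=False to fit
    the raw normalized series.

    A trace whose dynamic range is below ``flat_rel_range`` of its level
    (or whose fitted half-time falls outside the sampled window, or
    whose rate is pinned at a bound) is declared non-identifiable:
    converged=False with k and tc reported as NaN while a0 still gives
    the plateau -- the situation tabulated as 'N.D.' when the kinetics
    are too fast or too slow to resolve.
    """
    if leakage.size < 6:
        raise ValidationError("fit_sigmoid requires at least 6 points")
    series = smooth3(leakage) if smooth else leakage
    t = np.asarray(series.index, dtype=float)
    y = np.asarray(series, dtype=float)

    scale = max(float(np.max(np.abs(y))), 1e-12)
    if float(np.ptp(y)) < flat_rel_range * scale:
        return SigmoidFit(
            a0=float(np.mean(y)), k=float("nan"), tc=float("nan"),
            converged=False, residual_rms=float(np.std(y)),
        )

    a0_guess = float(np.max(y))
    half = a0_guess / 2.0
    tc_guess = float(t[np.argmin(np.abs(y - half))])
    t10 = float(t[np.argmax(y >= 0.1 * a0_guess)]) if np.any(y >= 0.1 * a0_guess) else float(t[0])
    t90 = float(t[np.argmax(y >= 0.9 * a0_guess)]) if np.any(y >= 0.9 * a0_guess) else float(t[-1])
    k_guess = 4.0 / max(t90 - t10, 4.0 / K_UPPER_BOUND)

    model = Model(_sigmoid_model)
    params = model.make_params(a0=a0_guess, k=k_guess, tc=tc_guess)
    params["a0"].set(min=0.0, max=A0_UPPER_BOUND)
    params["k"].set(min=0.0, max=K_UPPER_BOUND)
    params["tc"].set(min=0.0, max=float(t[-1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, t=t)

    a0 = float(result.params["a0"].value)
    k = float(result.params["k"].value)
    tc = float(result.params["tc"].value)
    se = {p: result.params[p].stderr for p in ("a0", "k", "tc")}
    se = {p: (float(v) if v is not None and np.isfinite(v) else float("nan")) for p, v in se.items()}
    rms = float(np.sqrt(np.mean(result.residual**2)))

    # Identifiability: the rate is meaningless if the rise is essentially
    # over before the first sample (less than ~12 % of it inside the
    # window), the plateau is never reached inside the window, or the rate
    # is pinned at a bound (Wald interval of k spanning the bound counts).
    k_lo = k - 2.0 * se["k"] if np.isfinite(se["k"]) else k
    k_hi = k + 2.0 * se["k"] if np.isfinite(se["k"]) else k
    rise_done_by = tc + (2.0 / k if k > 0 else np.inf)
    nonident = (
        rise_done_by <= t[0] or tc >= t[-1]
        or k >= 0.999 * K_UPPER_BOUND
        or k_lo < 0.0 < k or k_hi > K_UPPER_BOUND
        or not result.success
    )
    if nonident:
        return SigmoidFit(
            a0=a0, k=float("nan"), tc=float("nan"),
            se_a0=se["a0"], converged=False, residual_rms=rms,
        )
    return SigmoidFit(
        a0=a0, k=k, tc=tc,
        se_a0=se["a0"], se_k=se["k"], se_tc=se["tc"],
        converged=True, residual_rms=rms,
    )


def percent_lipid_mixing(
    sample: FluorescenceTrace,
    baseline: FluorescenceTrace,
    triton: FluorescenceTrace,
    correction_factor: float = 1.5,
    read_time: float = 10.0,
) -> MixingResult:
    """Percent lipid mixing at the read time of the probe-dilution assay.

    I_max is the observed post-Triton intensity multiplied by
    ``correction_factor``; the result is
    100 * (I_t - I_0,t) / (I_max,corr - I_0,t) evaluated at read_time.
    """
    if correction_factor <= 0:
        raise ValidationError(f"correction_factor: {correction_factor} must be > 0")
    it = sample.value_at(read_time)
    i0 = baseline.value_at(read_time)
    imax_corr = correction_factor * triton.value_at(read_time)
    denom = imax_corr - i0
    if denom <= 0:
        raise DegenerateReferenceError(
            f"corrected I_max ({imax_corr:g}) does not exceed I_0 ({i0:g}) at the read time"
        )
    pct = 100.0 * (it - i0) / denom
    return MixingResult(percent_mixing=float(pct), correction_factor=correction_factor,
                        read_time=read_time)
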