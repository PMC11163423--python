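"""End-to-end synthetic round trips: generator -> analysis -> report.

A RunConfig names one of the five assays, the generator parameters
(ground truth) and the analysis parameters; run_pipeline executes the
stages in order and returns a Report carrying both the truth and the
recovered values, so every number is traceable and the whole run is
replayable from the config digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import kinetics, monolayer, nmr, synthetic
from .datatypes import MixtureComposition
from .errors import BilayerkitError, ValidationError

logger = logging.getLogger("bilayerkit")

ASSAYS = ("leakage", "mixing", "nmr2h", "nmr31p", "isotherm")


@dataclass
class RunConfig:
    """One pipeline run: assay name, generator truth, analysis options."""

    assay: str
    generator: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"assay: {self.assay!r} not in {ASSAYS}")

    def digest(self) -> str:
        blob = json.dumps(
            {"assay": self.assay, "generator": self.generator,
             "analysis": self.analysis, "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Truth vs recovered values for one assay run."""

    assay: str
    config_digest: str
    truth: dict
    recovered: dict
    deltas: dict

    def to_dict(self) -> dict:
        return {
            "assay": self.assay,
            "config_digest": self.config_digest,
            "truth": self.truth,
            "recovered": self.recovered,
            "deltas": self.deltas,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=float, **kwargs)


def _deltas(truth: dict, recovered: dict) -> dict:
    out = {}
    for key, tv in truth.items():
        rv = recovered.get(key)
        if isinstance(tv, (int, float)) and isinstance(rv, (int, float)) \
                and tv is not None and np.isfinite(tv) and np.isfinite(rv):
            out[key] = rv - tv
    return out


def run_pipeline(config: RunConfig) -> Report:
    """Execute one assay's generator and analysis stages."""
    logger.info("run_pipeline assay=%s digest=%s", config.assay, config.digest())
    runner = {
        "leakage": _run_leakage,
        "mixing": _run_mixing,
        "nmr2h": _run_nmr2h,
        "nmr31p": _run_nmr31p,
        "isotherm": _run_isotherm,
    }[config.assay]
    try:
        truth, recovered = runner(config)
    except BilayerkitError as err:
        raise type(err)(
            f"[assay={config.assay} digest={config.digest()}] {err}"
        ) from err
    return Report(
        assay=config.assay,
        config_digest=config.digest(),
        truth=truth,
        recovered=recovered,
        deltas=_deltas(truth, recovered),
    )


def _run_leakage(config: RunConfig):
    gen = dict(config.generator)
    gen.setdefault("seed", config.seed)
    spec = synthetic.LeakageTraceSpec(**gen)
    sample, baseline, triton = synthetic.gen_leakage_traces(spec)
    series = kinetics.normalize_leakage(sample, baseline, triton)
    fit = kinetics.fit_sigmoid(series, smooth=config.analysis.get("smooth", True))
    truth = {"a0": spec.a0, "k": spec.k, "tc": spec.tc}
    recovered = {
        "a0": fit.a0, "k": fit.k, "tc": fit.tc,
        "se_a0": fit.se_a0, "se_k": fit.se_k, "se_tc": fit.se_tc,
        "converged": fit.converged, "residual_rms": fit.residual_rms,
    }
    return truth, recovered


def _run_mixing(config: RunConfig):
    gen = dict(config.generator)
    gen.setdefault("seed", config.seed)
    factor = config.analysis.get("correction_factor", gen.get("correction_factor", 1.5))
    read_time = config.analysis.get("read_time", gen.get("read_time", 10.0))
    sample, baseline, triton = synthetic.gen_mixing_traces(**gen)
    result = kinetics.percent_lipid_mixing(
        sample, baseline, triton, correction_factor=factor, read_time=read_time
    )
    truth = {"percent_mixing": 100.0 * gen["f_max"]}
    recovered = {"percent_mixing": result.percent_mixing}
    return truth, recovered


def _run_nmr2h(config: RunConfig):
    gen = dict(config.generator)
    gen.setdefault("seed", config.seed)
    prof_kwargs = {
        key: gen.pop(key)
        for key in ("n_carbons", "plateau_carbons", "methyl_ratio", "mean", "plateau_s")
        if key in gen
    }
    profile = synthetic.plateau_decay_profile(**prof_kwargs)
    spec = synthetic.PakeSpecInput(profile=profile, **gen)
    spectrum = synthetic.gen_pake_spectrum(spec)
    depaked = nmr.depake(
        spectrum,
        reg_strength=config.analysis.get("reg_strength"),
        broadening=config.analysis.get("broadening", spec.broadening),
    )
    recovered_profile = nmr.smoothed_profile(
        depaked, n_carbons=profile.n_carbons, chi_q=spec.chi_q
    )
    summary = nmr.chain_summary(recovered_profile, chi_q=spec.chi_q)
    truth = {
        "avg_S": float(np.mean(profile.s_cd)),
        "Lc_star": nmr.chain_extent(profile),
    }
    recovered = {"avg_S": summary.avg_S, "Lc_star": summary.Lc_star}
    return truth, recovered


def _run_nmr31p(config: RunConfig):
    gen = dict(config.generator)
    gen.setdefault("seed", config.seed)
    spec = synthetic.CSASpecInput(**gen)
    spectrum = synthetic.gen_csa_spectrum(spec)
    result = nmr.estimate_csa(spectrum)
    truth = {"delta_sigma": abs(spec.delta_sigma), "sigma_iso": spec.sigma_iso}
    recovered = {
        "delta_sigma": result.delta_sigma, "sigma_iso": result.sigma_iso,
        "converged": result.converged, "fit_rms": result.fit_rms,
    }
    return truth, recovered


def _run_isotherm(config: RunConfig):
    gen = dict(config.generator)
    gen.setdefault("seed", config.seed)
    mixture = gen.pop("mixture", None)
    spec = synthetic.IsothermModelSpec(**gen)
    iso = synthetic.gen_isotherm(spec)
    truth = {"lift_off_area": spec.lift_off_area}
    recovered = {}
    threshold = config.analysis.get("liftoff_threshold", 0.5)
    recovered["lift_off_area"] = monolayer.liftoff_area(iso, threshold=threshold)
    if mixture is not None:
        spec2 = synthetic.IsothermModelSpec(**mixture["component_2"])
        iso2 = synthetic.gen_isotherm(spec2)
        chi = MixtureComposition(
            tuple(mixture.get("components", ("c1", "c2"))),
            np.asarray(mixture["mole_fractions"], dtype=float),
        )
        excess_const = float(mixture.get("excess_area", 0.0))
        iso_mix = synthetic.gen_mixture_isotherm(
            iso, iso2, chi, excess_area_fn=lambda p: np.full_like(p, excess_const)
        )
        pi_lo = config.analysis.get("pi_lo", 0.0)
        pi_hi = config.analysis.get("pi_hi", 30.0)
        result = monolayer.gibbs_excess(iso_mix, iso, iso2, chi, pi_lo, pi_hi)
        from .constants import AREA_PRESSURE_TO_J_PER_MOL
        truth["delta_G_exc"] = excess_const * (pi_hi - pi_lo) * AREA_PRESSURE_TO_J_PER_MOL
        recovered["delta_G_exc"] = result.delta_G_exc
    return truth, recovered
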