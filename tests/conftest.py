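import numpy as np
import pytest

import bilayerkit as bk


@pytest.fixture(scope="session")
def popc_leakage_traces():
    """Noiseless leakage traces for the fastest-leaking PC system."""
    spec = bk.LeakageTraceSpec(a0=99.1, k=0.52, tc=0.87, t_end=40.0)
    return spec, bk.gen_leakage_traces(spec)


@pytest.fixture(scope="session")
def plateau_decay_spectrum():
    """Pake spectrum of a plateau-decay profile with mean <S> = 0.161."""
    profile = bk.plateau_decay_profile(mean=0.161)
    spec = bk.PakeSpecInput(profile=profile, broadening=0.5)
    return spec, bk.gen_pake_spectrum(spec)


@pytest.fixture(scope="session")
def single_doublet_spectrum():
    """Powder spectrum of a single CD2 carbon at |S| = 0.2, chi_q = 167 kHz."""
    profile = bk.OrderProfile([2], [0.2], deuteron_weights=[2.0])
    spec = bk.PakeSpecInput(profile=profile, broadening=0.3, spectral_width=80.0)
    return spec, bk.gen_pake_spectrum(spec)


@pytest.fixture(scope="session")
def component_isotherms():
    """Noiseless POPC-like and cholesterol-like compression isotherms."""
    iso1 = bk.gen_isotherm(bk.IsothermModelSpec(lift_off_area=111.0))
    iso2 = bk.gen_isotherm(bk.IsothermModelSpec(lift_off_area=48.0, collapse_pressure=50.0))
    return iso1, iso2


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
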