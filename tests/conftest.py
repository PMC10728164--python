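import numpy as np
import pytest

from ntdms import fixtures as fx
from ntdms.simulate import GeneratorConfig, generate_ms1
from ntdms.spectra import deconvolve

TNC_PROPORTIONS = (0.2, 0.2, 0.5, 0.1)   # 0/1/2/3 bound Ca


@pytest.fixture(scope="session")
def tnc_seq():
    return fx.tnc_sequence()


@pytest.fixture(scope="session")
def tnc_mixture_noiseless():
    """Noiseless TnC Ca-occupancy mixture MS1 (z 6-8) with ground truth."""
    species = tuple((fx.tnc_proteoform(k), p)
                    for k, p in enumerate(TNC_PROPORTIONS))
    cfg = GeneratorConfig(species=species, charge_center=7.0,
                          charge_range=(6, 8), seed=11)
    return generate_ms1(cfg)


@pytest.fixture(scope="session")
def tnc_mixture_deconvolved(tnc_mixture_noiseless):
    spectrum, truth = tnc_mixture_noiseless
    return deconvolve(spectrum), truth


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
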