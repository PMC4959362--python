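import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gradmatch import FHN, NoiseSpec, generate, regime_dataset
from gradmatch.synthetic_data import FHN_THETA, FHN_X0


@pytest.fixture(scope="session")
def fhn_reduced_dataset():
    """FitzHugh-Nagumo, 20 observations on [0, 10], noise sd (0.5, 0.4)."""
    return regime_dataset("fhn_cs_20", seed=101)


@pytest.fixture(scope="session")
def fhn_clean_dataset():
    """Dense, low-noise FitzHugh-Nagumo data for recovery checks."""
    return generate(FHN, FHN_THETA, FHN_X0, np.linspace(0, 10, 50),
                    NoiseSpec("additive_fixed_sd", (0.05, 0.05), seed=5))


@pytest.fixture(scope="session")
def ptp_dataset():
    """Pathway data on the 15-point grid at average SNR 10 (additive)."""
    return regime_dataset("ptp_snr", seed=201, snr=10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
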