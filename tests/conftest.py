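import numpy as np
import pytest

from osteosense import MCConfig, OpticalProperties, ProbeGeometry
from osteosense.acquisition import AcquisitionConfig
from osteosense.circuits import TIAParams

# Table of bone optical properties (cm^-1) and reference collected
# fractions (permille) used throughout the suite.
BONE_CELLS = [
    ("cancellous", 940, OpticalProperties(0.216, 28.6, 0.9), 0.152),
    ("cancellous", 1310, OpticalProperties(0.833, 17.3, 0.9), 0.120),
    ("cortical", 940, OpticalProperties(0.223, 16.4, 0.9), 0.149),
    ("cortical", 1310, OpticalProperties(0.920, 11.3, 0.9), 0.0955),
]


@pytest.fixture(scope="session")
def geom():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def tia():
    return TIAParams()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_mc(n_photons=200_000, seed=3):
    return MCConfig(n_photons=n_photons, rng_seed=seed)
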