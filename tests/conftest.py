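import numpy as np
import pytest

from mushbody.circuit import ground_truth_params
from mushbody.synthetic import GroundTruth, default_schema


@pytest.fixture(scope="session")
def params():
    return ground_truth_params()


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def low_noise_truth(params):
    return GroundTruth(params=params, noise_sd=0.2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
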