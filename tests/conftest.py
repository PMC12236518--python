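import numpy as np
import pytest

from stabscreen import fixtures
from stabscreen.synthdata import DSFGenParams


@pytest.fixture(scope="session")
def control_params() -> DSFGenParams:
    return fixtures.dsf_params("control")


@pytest.fixture(scope="session")
def noiseless_control(control_params) -> DSFGenParams:
    return fixtures.dsf_params("control", noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
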