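import numpy as np
import pytest

import ssmdiag as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study_params():
    """The baseline parameter set of the simulation study."""
    return sd.SSMParams(rho=0.7, sigma_eta=0.2, sigma_eps=0.1, x0=0.0)


@pytest.fixture
def short_series(study_params):
    return sd.simulate_ssm(study_params, 40, seed=7)
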