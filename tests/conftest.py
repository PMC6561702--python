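import numpy as np
import pytest
from hypothesis import settings

import cliffwind as cw

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def obs_table():
    """A mid-sized synthetic landing table with the default true model."""
    return cw.generate_observations(cw.SimulationConfig(n_attempts=2000, seed=1))


@pytest.fixture(scope="session")
def glmm_fit(obs_table):
    """The default mixed-model fit on the shared table."""
    fit = cw.fit_landing_glmm(obs_table)
    assert fit.converged
    return fit


@pytest.fixture
def rng():
    return np.random.default_rng(0)
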