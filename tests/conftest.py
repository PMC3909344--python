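import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mechstates import MechanicalStateHMM, ModelParams, SimConfig, simulate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_truth():
    """One synthetic recording at the default study conditions."""
    return simulate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_fit(default_truth, default_params):
    """Decoding of the default synthetic recording."""
    return MechanicalStateHMM(default_truth.diameter, default_truth.pressure,
                              default_params).fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_observations(rng, n, params=None):
    """Random but physically plausible observation arrays (d, dd, dp)."""
    params = params or ModelParams()
    d = rng.uniform(3.0, 15.0, n)
    dd = rng.normal(0.0, 3.0 * params.sigma_ddot, n)
    dp = rng.normal(0.0, 3.0 * params.sigma_pdot, n)
    return d, dd, dp
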