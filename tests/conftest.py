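import pytest
from hypothesis import HealthCheck, settings

from renalcea.markov import ModelSettings
from renalcea.parameters import default_parameters, draw_from_means
from renalcea.reporting import run_base_case
from renalcea.sensitivity import run_psa

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

#: seed used everywhere a test needs one fixed stream
TEST_SEED = 1234


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_draw(params):
    return draw_from_means(params)


@pytest.fixture(scope="session")
def model_settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_case(params):
    return run_base_case(params)


@pytest.fixture(scope="session")
def psa_samples(params):
    """The default PSA run: 1000 Monte-Carlo iterations, fixed seed."""
    return run_psa(params, iterations=1000, seed=TEST_SEED)
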