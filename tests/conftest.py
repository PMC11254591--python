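import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    """Calibrated default parameter set, built from the published targets."""
    from pccost.synthetic_data import build_default_parameter_set

    return build_default_parameter_set()


@pytest.fixture(scope="session")
def components(default_params):
    from pccost import markov_cohort as mc

    return mc.state_components(default_params)
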