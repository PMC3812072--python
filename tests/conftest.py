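import pytest
from hypothesis import HealthCheck, settings

from matswitch import default_params, make_named_config, perfect_directionality_params

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_STRAIN_NAMES = [
    "h90", "h09", "h09_swapped", "h90_swapped",
    "2xSRE2", "2xSRE3", "SRE2del", "SRE3del", "SRE2del_SRE3del",
]


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def perfect_params():
    return perfect_directionality_params()


@pytest.fixture(scope="session")
def h90():
    return make_named_config("h90")


@pytest.fixture(scope="session")
def h09():
    return make_named_config("h09")
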