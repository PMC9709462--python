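import pytest
from hypothesis import HealthCheck, settings

from ohra import MethodConfig, default_registry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> MethodConfig:
    return MethodConfig.default()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def mn_profile(registry):
    return registry["Manganese and inorganic compounds"]


@pytest.fixture(scope="session")
def benzene_profile(registry):
    return registry["Benzene"]
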