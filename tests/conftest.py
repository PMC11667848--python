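import pytest
from hypothesis import HealthCheck, settings

import omppricer as op

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> op.CaseConfig:
    """The bundled lumasiran / PH1 case."""
    return op.load_lumasiran()


@pytest.fixture(scope="session")
def constants(config) -> op.GlobalConstants:
    return config.constants


@pytest.fixture(scope="session")
def raw_fixture_dict(config) -> dict:
    """The fixture as a plain mapping, for mutation-based schema tests."""
    return config.model_dump(mode="json")
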