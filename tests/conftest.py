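import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from obscreen import Period, load_period_schema  # noqa: E402


@pytest.fixture(scope="session")
def schemas():
    return {p: load_period_schema(p) for p in Period}


@pytest.fixture(scope="session")
def fv_schema(schemas):
    return schemas[Period.FIRST_VISIT]


@pytest.fixture(scope="session")
def st_schema(schemas):
    return schemas[Period.SECOND_TRIMESTER]
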