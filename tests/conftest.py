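import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from acetoledger.scenarios import build_co, build_high_h2, build_low_h2  # noqa: E402


@pytest.fixture(scope="session")
def high_h2():
    return build_high_h2()


@pytest.fixture(scope="session")
def low_h2():
    return build_low_h2()


@pytest.fixture(scope="session")
def co():
    return build_co()


@pytest.fixture(scope="session")
def all_scenarios(high_h2, low_h2, co):
    return {"high_h2": high_h2, "low_h2": low_h2, "co": co}
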