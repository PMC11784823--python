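import pytest
from hypothesis import HealthCheck, settings

from fuzzyfmea import FuzzySystem, default_rulebase, load_case_study, run_case_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fis():
    return FuzzySystem.default()


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()


@pytest.fixture(scope="session")
def bundle():
    return load_case_study()


@pytest.fixture(scope="session")
def case_table():
    return run_case_study()
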