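import pytest
from hypothesis import HealthCheck, settings

from neoprog.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort157():
    """Default-condition synthetic cohort at the study's sample size."""
    return generate_cohort(GeneratorConfig(n=157, seed=42))


@pytest.fixture(scope="session")
def cohort1000():
    """Larger synthetic cohort for stochastic structural checks."""
    return generate_cohort(GeneratorConfig(n=1000, seed=7))
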