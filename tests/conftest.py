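import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "paftool",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("paftool")


@pytest.fixture(scope="session")
def small_study():
    """A seeded synthetic study shared by pipeline tests."""
    from paftool.synthetic import GeneratorConfig, generate_study

    return generate_study(GeneratorConfig(seed=7, n_records=500))


@pytest.fixture(scope="session")
def survey_10k():
    """Survey records at n=10^4 per sex with their ground-truth prevalence."""
    from paftool.synthetic import GeneratorConfig, generate_survey

    config = GeneratorConfig(seed=11, n_records=10_000)
    records, truth = generate_survey(config)
    return records, truth
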