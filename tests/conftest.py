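import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def demo_stream():
    from fluidevents.datasets import aerial_combat_demo
    return aerial_combat_demo()


@pytest.fixture
def demo_reference():
    from fluidevents.datasets import aerial_combat_reference_trace
    return aerial_combat_reference_trace()


@pytest.fixture(scope="session")
def small_cohort():
    """Ten model-driven participants, 400 bins each (seeded)."""
    from fluidevents.synthetic import GeneratorParams, generate_cohort
    return generate_cohort(GeneratorParams(n_participants=10,
                                           bins_per_stream=400, seed=11))
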