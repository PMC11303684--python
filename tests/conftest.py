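import pytest
from hypothesis import HealthCheck, settings

from chitosim import ChainPopulation, GeneratorParams, generate_random, make_ideal_repeat

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def random_pop_032():
    """500 random-PA chains of DP 1000 at FA 0.32 (the standard library scale)."""
    return generate_random(GeneratorParams(500, 1000, 0.32, seed=11))


@pytest.fixture()
def dda_pop():
    """500 ideal (DDA)-repeat chains of DP 999."""
    return ChainPopulation(
        [make_ideal_repeat("DDA", 999, id=f"dda_{i}") for i in range(500)]
    )
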