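import pytest
from hypothesis import HealthCheck, settings

from dendrosoma import SimConfig, generate_architecture, generate_genome

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, genome_length=60_000, n_genes=10, mu_per_meter=5e-5)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def arch7():
    return generate_architecture(seed=5)
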