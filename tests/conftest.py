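import pytest
from hypothesis import HealthCheck, settings

from cugscribe.synthetic_data import (
    SimulationConfig,
    simulate_query_genome,
    simulate_reference_bundle,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_families=3,
    family_length=(90, 130),
    n_standard_species=8,
    n_aycu_species=8,
    n_cug_columns=6,
    flank=120,
    genes_per_contig=3,
    n_query_genes_per_family=1,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_bundle(small_config):
    bundle, truth = simulate_reference_bundle(small_config)
    return bundle, truth


@pytest.fixture(scope="session")
def small_genomes(small_bundle, small_config):
    bundle, _ = small_bundle
    out = {}
    for label in ("standard", "aycu"):
        out[label] = simulate_query_genome(bundle, label, small_config, seed=77)
    return out
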