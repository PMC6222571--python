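import pytest

from acylqtl.population import (
    PopulationConfig,
    build_marker_map,
    default_causal_loci,
    simulate_f2,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def pop_config():
    """Default effect structure at reduced marker density (fast to simulate)."""
    return PopulationConfig(n_individuals=128, n_markers=800, seed=11)


@pytest.fixture(scope="session")
def causal_loci():
    return default_causal_loci()


@pytest.fixture(scope="session")
def population(pop_config, causal_loci):
    """(genotypes, phenotypes) for the default synthetic cross."""
    mm = build_marker_map(pop_config)
    g = simulate_f2(mm, causal_loci, pop_config)
    ph = simulate_phenotypes(g, causal_loci, pop_config)
    return g, ph
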