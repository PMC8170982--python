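import pytest

from islandscope import (
    NeighborhoodConfig,
    RenderConfig,
    SimConfig,
    default_vocabulary,
    simulate_genome_set,
)


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome set shared across tests: 6 references,
    60 backbone genes, one planted island."""
    cfg = SimConfig(
        n_reference_genomes=6,
        backbone_genes=60,
        island_count=1,
        island_span=(10_000, 15_000),
        seed=11,
    )
    return simulate_genome_set(cfg)


@pytest.fixture(scope="session")
def small_render_config():
    # compact canvas keeps unit tests fast; the renderer is size-agnostic
    return RenderConfig(width=96, height=96)


@pytest.fixture(scope="session")
def neighborhood_config():
    return NeighborhoodConfig()
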