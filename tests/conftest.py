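"""Shared fixtures: one small simulated dataset reused across modules."""
import pytest

from endmap.synthetic_data import (
    SimConfig,
    generate_genome,
    simulate_term_libraries,
    simulate_tss_libraries,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_genes=30, seed=11)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """(genome, annotation, truth) for a 30-gene toy genome."""
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def sim_drna(sim_dataset, sim_config):
    _, _, truth = sim_dataset
    tracks = simulate_tss_libraries(truth, sim_config)
    return (
        [t for t in tracks if t.library_type == "TAP_PLUS"],
        [t for t in tracks if t.library_type == "TAP_MINUS"],
    )


@pytest.fixture(scope="session")
def sim_term(sim_dataset, sim_config):
    _, _, truth = sim_dataset
    return simulate_term_libraries(truth, sim_config)
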