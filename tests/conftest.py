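"""Shared fixtures: one default-scale synthetic dataset per session, plus a
tiny dataset for I/O and CLI tests."""

from __future__ import annotations

import pytest

from polyrgene import simulate as sim

SESSION_SEED = 7


@pytest.fixture(scope="session")
def config() -> sim.SimulationConfig:
    return sim.SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def ancestors(config):
    return sim.generate_ancestors(config)


@pytest.fixture(scope="session")
def genome(config, ancestors):
    anc_a, anc_b, loci = ancestors
    return sim.generate_octoploid(anc_a, anc_b, loci, config)


@pytest.fixture(scope="session")
def population(config, genome):
    return sim.simulate_expression_and_genotypes(genome, config)


@pytest.fixture(scope="session")
def tiny_config() -> sim.SimulationConfig:
    return sim.SimulationConfig(
        seed=13,
        n_groups=2,
        genes_per_chromosome=12,
        markers_per_chromosome=30,
        progeny_per_family=8,
        n_families=2,
        n_eqtl_genes=2,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    anc_a, anc_b, loci = sim.generate_ancestors(tiny_config)
    genome = sim.generate_octoploid(anc_a, anc_b, loci, tiny_config)
    pop = sim.simulate_expression_and_genotypes(genome, tiny_config)
    return genome, pop
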