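"""Shared fixtures: small synthetic populations generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from strainscope import (
    CoreAlignment,
    PopulationSimSpec,
    hamming_distance,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_spec() -> PopulationSimSpec:
    """Tiny population for plumbing tests: 8 genomes/subspecies, ~27 kb
    of genes, a 5 kb island, a scaled-down operon."""
    return PopulationSimSpec(
        n_genomes_per_subspecies=(8, 8, 8, 8),
        n_genes=90,
        gene_length=300,
        ancestral_length=36_000,
        island_length=5_000,
        island_present_in=("ErEurope", 0.5),
        block_length=500,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_spec):
    return simulate_population(small_spec)


@pytest.fixture(scope="session")
def small_alignment(small_population) -> CoreAlignment:
    labels, rows = small_population.core_alignment()
    return CoreAlignment(labels, rows)


@pytest.fixture(scope="session")
def small_distances(small_alignment):
    return hamming_distance(small_alignment)


@pytest.fixture(scope="session")
def clustered_spec() -> PopulationSimSpec:
    """Population sized for clustering tests: 15 genomes/subspecies over
    a ~36 kb core alignment; no island to keep generation fast."""
    return PopulationSimSpec(
        n_genomes_per_subspecies=(15, 15, 15, 15),
        n_genes=80,
        gene_length=600,
        ancestral_length=56_000,
        island_present_in=None,
        operon_deleted_in=None,
        block_length=1_000,
        seed=9,
    )


@pytest.fixture(scope="session")
def clustered_population(clustered_spec):
    return simulate_population(clustered_spec)


@pytest.fixture(scope="session")
def clustered_distances(clustered_population):
    labels, rows = clustered_population.core_alignment()
    return hamming_distance(CoreAlignment(labels, rows))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
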