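"""Shared fixtures: small deterministic genomes, hairpins and read stacks."""

from __future__ import annotations

import numpy as np
import pytest

from mirdup.config import FoldConfig, SimConfig
from mirdup.synthetic import make_hairpin


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_sim_config() -> SimConfig:
    """A reduced study: 2 scaffolds x 40 kb, 4 families, no clusters."""
    return SimConfig(
        seed=7, n_scaffolds=2, scaffold_length=40_000, n_families=4,
        copies_per_family=[1, 2, 3, 1], n_duplicated_clusters=0,
        cluster_composition={}, unit_spacing=4_000,
        background_fraction=0.0, jitter_prob=0.0)


@pytest.fixture
def pair_count_fold() -> FoldConfig:
    return FoldConfig(energy_model="pair_count")


@pytest.fixture
def perfect_hairpin(rng) -> str:
    """A 22-nt mature + 8-nt loop + perfect complement (52 nt)."""
    return make_hairpin("ACGTACGTACGTACGTACGTAC", 8, bulges=0, rng=rng)
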