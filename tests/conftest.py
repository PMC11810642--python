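"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from polyhybrid.config import GENOTYPES, SimulationConfig, VarietySpec
from polyhybrid.simulate import simulate_all


def six_varieties(n: int = 3) -> tuple[VarietySpec, ...]:
    return tuple(
        VarietySpec(g.name, g.r_copies, g.c_copies, g.mito_origin, n)
        for g in GENOTYPES.values()
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=101,
        n_chromosomes=2,
        genes_per_chromosome=40,
        agp_fraction=0.8,
        varieties=six_varieties(3),
        sequencing_depth=2e5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)
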