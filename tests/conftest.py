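"""Shared fixtures: small synthetic panels built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from genarch import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    """A desk-scale panel: 60 lines, two autosome arms and an X, one
    diverged polymorphic inversion on 2L."""
    return sim.SimulationConfig(
        n_lines=60,
        contigs=[
            sim.ContigSpec("2L", 120_000),
            sim.ContigSpec("2R", 120_000),
            sim.ContigSpec("X", 120_000, is_x=True),
        ],
        inversions=[
            sim.InversionSpec("In(2L)t", "2L", 20_000, 100_000,
                              karyotype_frequency=0.25, divergence=0.01),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_founders(small_config):
    return sim.simulate_founders(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_founders):
    matrix, panel = sim.simulate_inbreeding(small_founders, small_config)
    return matrix, panel


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
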