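"""Shared fixtures: simulated datasets reused across test modules.

Heavy simulations (genome + homology search) are session-scoped so the
discovery tests and the acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from telandscape.synthetic_data import (
    AgePeak,
    SimulationConfig,
    make_master,
    plant_copies,
)
from telandscape.tree import SpeciesTree

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def master_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def master(master_config):
    return make_master(master_config)


@pytest.fixture(scope="session")
def shallow_tree() -> SpeciesTree:
    """Two species that split almost immediately: species-level masters are
    effectively identical to the family master."""
    return SpeciesTree.from_newick("(A:0.001,B:0.001);")


@pytest.fixture(scope="session")
def burst_sim(shallow_tree):
    """Planted copies at fixed age 2.5 Myr (k = 0.05 at 1e-8/site/yr),
    no truncation: the discovery benchmark dataset."""
    cfg = SimulationConfig(
        seed=11,
        copies_per_species=20,
        truncation_prob=0.0,
        age_distribution=(AgePeak(mean=2.5, sd=0.0),),
    )
    return plant_copies(shallow_tree, cfg)


@pytest.fixture(scope="session")
def burst_hits(burst_sim):
    from telandscape.element_discovery import homology_search

    return homology_search(
        burst_sim.genomes["A"], burst_sim.master.sequence, genome_id="A"
    )


@pytest.fixture(scope="session")
def zero_divergence_sim():
    """Zero-age copies on a zero-depth tree: every copy is an exact replica
    of the master."""
    cfg = SimulationConfig(
        seed=13,
        copies_per_species=10,
        truncation_prob=0.0,
        background_length=30_000,
        age_distribution=(AgePeak(mean=0.0, sd=0.0),),
    )
    return plant_copies(SpeciesTree.from_newick("(A:0,B:0);"), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
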