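import dataclasses

import numpy as np
import pytest

from nucphase.simulate import (
    SimulationConfig,
    dyad_table,
    genes_to_table,
    simulate_condition,
)


@pytest.fixture(scope="session")
def small_cfg():
    return dataclasses.replace(SimulationConfig(), n_genes=60)


@pytest.fixture(scope="session")
def wt_small(small_cfg):
    return simulate_condition(small_cfg, "WT", 11)


@pytest.fixture(scope="session")
def mut_small(small_cfg):
    return simulate_condition(small_cfg, "spt6-F249K-like", 11)


@pytest.fixture(scope="session")
def full_cfg():
    """The default study conditions (250 genes, 200 transcribed)."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def wt_full(full_cfg):
    return simulate_condition(full_cfg, "WT", 1)


@pytest.fixture(scope="session")
def mut_full(full_cfg):
    return simulate_condition(full_cfg, "spt6-F249K-like", 1)


def transcribed_table(sim):
    genes = genes_to_table(sim.genes)
    mask = np.array([g.transcribed for g in sim.genes])
    return genes[mask]


def nontranscribed_table(sim):
    genes = genes_to_table(sim.genes)
    mask = np.array([g.transcribed for g in sim.genes])
    return genes[~mask]


def high_confidence_dyads(sim):
    """+1-nucleosome ground-truth dyads of transcribed genes."""
    return dyad_table(sim.genes, max_nuc_index=0, transcribed_only=True)
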