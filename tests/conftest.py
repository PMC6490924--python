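"""Shared fixtures: reduced-grid lookup tables and a small adaptive grid.

Everything here is generated at test time; the reduced presets (coarse
position grid, 1000 Monte-Carlo trials per cell, few-level adaptive grid)
keep per-module tests fast while exercising the same code paths as the
full-resolution objects.
"""

import pytest

import colormat as cm
from colormat.questplus_engine import QuestParameterGrid


@pytest.fixture(scope="session")
def euclid_table():
    return cm.build_reduced_table("euclidean", seed=101)


@pytest.fixture(scope="session")
def cityblock_table():
    return cm.build_reduced_table("cityblock", seed=102)


@pytest.fixture(scope="session")
def tables(euclid_table, cityblock_table):
    return {"euclidean": euclid_table, "cityblock": cityblock_table}


@pytest.fixture(scope="session")
def small_grid():
    """Few-level adaptive grid: large enough to be informative, fast to scan."""
    return QuestParameterGrid.coarse()


@pytest.fixture(scope="session")
def linear_observer():
    return cm.GeneratingObserver(0.5, cm.linear_mapping(1.0), "euclidean")


@pytest.fixture(scope="session")
def short_session(linear_observer, small_grid, euclid_table):
    """Two simulated blocks (540 trials) from a w=0.5 linear observer."""
    design = cm.SessionDesign(n_blocks=2)
    return cm.simulate_session(linear_observer, design, small_grid,
                               euclid_table, seed=42)
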