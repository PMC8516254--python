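import numpy as np
import pandas as pd
import pytest

from hare import (
    FounderSet,
    HaplotypePanel,
    SimScenario,
    simulate_diverse_panel,
    simulate_expression,
)


@pytest.fixture(scope="session")
def founders():
    return FounderSet(n_founders=26, n_ranges=40)


@pytest.fixture
def toy_panel():
    """4 lines, 2 ranges; haplotypes [A,A,B,B] coded as [0,0,1,1] at rr0."""
    table = pd.DataFrame(
        {"rr0": [0, 0, 1, 1], "rr1": [0, 1, 0, 1]},
        index=["l1", "l2", "l3", "l4"],
    )
    return HaplotypePanel(table)


@pytest.fixture(scope="session")
def diverse_panel(founders):
    return simulate_diverse_panel(founders, n_lines=200, mosaic_block_mean=15.0, seed=42)


@pytest.fixture(scope="session")
def sim_two_tissue(diverse_panel):
    """30 genes, two tissues with independent trans effects."""
    scenario = SimScenario(n_genes=30, n_tissues=2, trans_tissue_corr=0.0, seed=7)
    return simulate_expression(diverse_panel, scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
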