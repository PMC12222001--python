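import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from mitocomp.simulate import SimulationConfig, balanced_tree, simulate_mitogenome_set


@pytest.fixture(scope="session")
def tree4() -> str:
    return balanced_tree(4, branch_length=0.05)


@pytest.fixture(scope="session")
def tree8() -> str:
    return balanced_tree(8, branch_length=0.05)


@pytest.fixture(scope="session")
def sim_set(tree4):
    """One default-condition mitogenome collection shared across tests."""
    cfg = SimulationConfig(tree=tree4, seed=11)
    genomes, alignments, truth = simulate_mitogenome_set(cfg)
    return cfg, genomes, alignments, truth


@pytest.fixture(scope="session")
def genome(sim_set):
    return sim_set[1][0]
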