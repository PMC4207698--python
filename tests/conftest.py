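import numpy as np
import pandas as pd
import pytest

from paramodiv.simulate import simulate_bisse_tree
from paramodiv.trees import Phylogeny


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — the canonical worked example."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def eight_tip():
    """A simulated 8-tip binary-state tree with both states at the tips."""
    tree, states = simulate_bisse_tree([0.8, 1.2, 0.2, 0.1, 0.1, 0.07],
                                       stop_taxa=8, rng=5)
    assert set(states.values) == {0, 1}
    return tree, states


@pytest.fixture
def specimen_frame():
    """Two species × two specimens on a 4-tip balanced tree."""
    tree = Phylogeny.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
    table = pd.DataFrame({
        "specimen_id": ["a1", "a2", "b1", "b2"],
        "species_id": ["A", "A", "B", "B"],
        "paramo": [1, 1, 0, 0],
        "microhabitat": ["exposed", "exposed", "sheltered", "sheltered"],
        "altitude": [3500.0, 3600.0, 1500.0, 1600.0],
        "pinnae_length": [4.0, 5.0, 30.0, 28.0],
        "leaves_per_frond": [40, 45, 12, 14],
    })
    return tree, table
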