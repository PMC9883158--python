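import warnings

import numpy as np
import pandas as pd
import pytest

from phylocoev.simulate import (
    SyntheticConfig,
    make_dataset,
    simulate_coords,
    simulate_tree,
)
from phylocoev.trees import Phylogeny, parse_trees

warnings.filterwarnings("ignore", category=RuntimeWarning, module="phylocoev")


@pytest.fixture(scope="session")
def three_tip_tree() -> Phylogeny:
    return parse_trees("((A:1,B:1):1,C:2);").trees[0]


@pytest.fixture(scope="session")
def bd_tree_20() -> Phylogeny:
    return simulate_tree(20, seed=42)


@pytest.fixture(scope="session")
def bd_tree_50() -> Phylogeny:
    return simulate_tree(50, seed=7)


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    nwk = "(" + ",".join(f"t{i}:{depth}" for i in range(1, n + 1)) + ");"
    return parse_trees(nwk).trees[0]


@pytest.fixture(scope="session")
def dataset_small():
    return make_dataset(SyntheticConfig(n_tips=40, seed=3))


@pytest.fixture(scope="session")
def coords_20() -> np.ndarray:
    return simulate_coords(20, (-45, 25, 95, 180), seed=5)


def society_table(tree, y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": tree.tip_labels,
            "political_authority": y[:, 0],
            "religious_authority": y[:, 1],
        }
    )
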