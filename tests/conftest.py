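import numpy as np
import pandas as pd
import pytest

from radkit.trees import DatedTree
from radkit.qmatrix import QMatrix
from radkit.simulate import simulate_bd


@pytest.fixture
def balanced4():
    """4-tip ultrametric tree, root age 2.5."""
    return DatedTree.from_newick("((A:1.0,B:1.0):1.5,(C:2.0,D:2.0):0.5);")


@pytest.fixture
def tree5():
    """5-tip ultrametric tree with ladder on one side, root age 3."""
    return DatedTree.from_newick(
        "(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")


@pytest.fixture
def q2():
    return QMatrix.er(("0", "1"), 0.7)


@pytest.fixture
def yule33():
    tree, _ = simulate_bd(0.575, 0.0, n_tips=33, seed=7)
    return tree


@pytest.fixture
def mk_trait4():
    return pd.Series({"A": "0", "B": "1", "C": "1", "D": "0"})
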