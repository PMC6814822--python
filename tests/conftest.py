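import numpy as np
import pytest

from ssdevol import read_tree, simulate_tree


@pytest.fixture
def cherry3():
    """3-tip ultrametric tree: ((A:1,B:1):1,C:2);"""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star3():
    return read_tree("(A:2,B:2,C:2);")


@pytest.fixture
def yule20():
    return simulate_tree(20, 10.0, seed=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(n_tips, depth, seed):
    return simulate_tree(n_tips, depth, seed=seed)
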