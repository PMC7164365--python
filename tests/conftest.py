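import numpy as np
import pytest

import terebra as tb


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); - ultrametric, height 2."""
    return tb.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return tb.read_newick(
        "(((A:0.6,B:0.6):0.9,(C:1.0,D:1.0):0.5):0.7,E:2.2);")


@pytest.fixture
def balanced16_tree():
    """Perfectly balanced ultrametric 16-tip tree, height 4."""
    def rec(depth, prefix):
        if depth == 0:
            return prefix
        return f"({rec(depth-1, prefix+'0')}:1,{rec(depth-1, prefix+'1')}:1)"
    return tb.read_newick(rec(4, "t") + ";")


@pytest.fixture
def single_regime_painting(five_tip_tree):
    t = five_tip_tree
    paint = [None if v == t.root else [("r", t.lengths[v])]
             for v in range(t.n_nodes)]
    return tb.RegimePaintedTree(t, paint)


def make_yule(n_tips, seed, lam=0.1):
    return tb.simulate_yule_tree(lam, n_tips, seed)


@pytest.fixture
def yule100():
    return make_yule(100, seed=1234)
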