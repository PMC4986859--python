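import math

import numpy as np
import pytest

from leafsandwich.datasets import fixture_tree, load_table1


def brownian_trait(tree, rng, sigma=1.0, root=0.0) -> dict:
    """Simulate Brownian motion along a tree; returns tip label -> value."""
    vals = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd._bm = root
        else:
            bl = nd.edge.length or 0.0
            nd._bm = nd.parent_node._bm + rng.normal(0, sigma * math.sqrt(bl))
        if nd.is_leaf():
            vals[nd.taxon.label] = nd._bm
    return vals


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def species_tree():
    return fixture_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20150211)
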