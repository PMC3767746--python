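import numpy as np
import pytest
from skbio import DistanceMatrix

from redlistdiv import simulate_yule_tree


@pytest.fixture
def yule16():
    return simulate_yule_tree(16, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_distance_matrix(n, rng, labels=None):
    """Random symmetric hollow matrix with entries in (0, 1)."""
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    ids = labels or [f"t{i}" for i in range(n)]
    return DistanceMatrix(m, ids=ids)


def root_path_edges(leaf):
    """Edge identity set along a tip's path to the root (oracle helper)."""
    out = set()
    node = leaf
    while node.parent_node is not None:
        out.add(id(node))
        node = node.parent_node
    return out


def brute_force_branch_sum(tree, tips):
    """Independent PD oracle: size of the union of root-to-tip edge
    sets, weighted by branch length (include_root=True convention)."""
    wanted = set(tips)
    union = set()
    lengths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            lengths[id(node)] = node.edge.length or 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in wanted:
            union |= root_path_edges(leaf)
    return sum(lengths[e] for e in union)
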