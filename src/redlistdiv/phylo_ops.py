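"""Consensus trees and branching-pattern cladograms.

A sample of phylogenies over one tip set is reduced to a majority-rule
consensus (keep exactly the bipartitions occurring in strictly more
than a threshold fraction of trees), and a topology is turned into a
cladogram by assigning node heights from the branching pattern alone
and rescaling so that the shortest positive branch has length 1.
"""

from __future__ import annotations

from collections import Counter

import dendropy

__all__ = [
    "tip_bipartitions",
    "majority_consensus",
    "cladogram_transform",
]


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def tip_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a tree as canonical tip-label sets.

    Each internal edge splits the tips in two; the canonical side is
    the one *not* containing the lexicographically smallest tip label.
    Trivial splits (single tips, the full set) are omitted.
    """
    all_tips = _leaf_labels(tree)
    ref = min(all_tips)
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            tips = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = tips
            if node.parent_node is None:
                continue
            side = all_tips - tips if ref in tips else tips
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
    return out


def majority_consensus(
    trees: list[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus of trees sharing one tip set.

    Keeps exactly the bipartitions whose frequency across the sample
    is strictly greater than ``threshold``; the result may be
    non-binary and carries no branch lengths.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not (0.5 <= threshold < 1.0):
        raise ValueError("threshold must be in [0.5, 1)")
    tipsets = [_leaf_labels(t) for t in trees]
    if any(ts != tipsets[0] for ts in tipsets[1:]):
        raise ValueError("trees have mismatched tip sets")
    all_tips = tipsets[0]

    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(tip_bipartitions(t))
    n = len(trees)
    kept = [s for s, c in counts.items() if c / n > threshold]

    # strict-majority splits are pairwise compatible: nest by size
    ref = min(all_tips)
    clades = []
    for side in kept:
        clades.append(side if ref not in side else all_tips - side)
    clades.sort(key=lambda s: (-len(s), tuple(sorted(s))))

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    node_tips: dict[int, frozenset[str]] = {id(root): all_tips}
    internal = [root]
    leaf_nodes = {}
    for lab in sorted(all_tips):
        leaf = dendropy.Node()
        leaf.taxon = tns.new_taxon(lab)
        root.add_child(leaf)
        leaf_nodes[lab] = leaf
        node_tips[id(leaf)] = frozenset([lab])
    for clade in clades:
        # smallest current internal node containing the clade
        host = min(
            (nd for nd in internal if clade <= node_tips[id(nd)]),
            key=lambda nd: len(node_tips[id(nd)]),
        )
        new = dendropy.Node()
        node_tips[id(new)] = clade
        movers = [c for c in host.child_nodes() if node_tips[id(c)] <= clade]
        for c in movers:
            host.remove_child(c)
            new.add_child(c)
        host.add_child(new)
        internal.append(new)
    return tree


def cladogram_transform(
    tree: dendropy.Tree, method: str = "grafen"
) -> dendropy.Tree:
    """Assign branch lengths to a topology from its branching pattern.

    ``grafen``: node height = number of descendant tips - 1 (tips sit
    at height 0).  ``node_depth``: node height = maximum number of
    nodes passed on the way down to a tip.  Branch length = parent
    height - child height, then all lengths are rescaled so the
    minimum positive branch length is exactly 1.

    Existing branch lengths on the input are ignored; the input tree is
    not modified.
    """
    if method not in ("grafen", "node_depth"):
        raise ValueError(f"unknown cladogram method: {method!r}")
    out = tree.clone(depth=1)
    if len(out.leaf_nodes()) < 2:
        raise ValueError("cladogram transform needs at least 2 tips")
    height: dict[int, float] = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            height[id(node)] = 0.0
        elif method == "grafen":
            height[id(node)] = sum(1 for _ in node.leaf_iter()) - 1
        else:
            height[id(node)] = 1 + max(height[id(c)] for c in node.child_nodes())
    positive = []
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        length = height[id(node.parent_node)] - height[id(node)]
        node.edge.length = length
        if length > 0:
            positive.append(length)
    scale = min(positive)
    for node in out.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= scale
    return out
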