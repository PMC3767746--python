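"""UPGMA functional dendrograms.

Builds ultrametric trees from trait dissimilarities by average-linkage
agglomeration: at each step the pair of clusters with the smallest
mean pairwise distance is merged at a height of half that distance, so
every tip lies at the same distance from the root.  Ties on the
minimum linkage distance are broken deterministically by merging the
pair whose pooled, lexicographically sorted label tuple is smallest.
"""

from __future__ import annotations

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = ["upgma", "is_ultrametric", "cophenetic_matrix"]


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Returns a rooted, strictly binary, ultrametric dendropy tree whose
    tip labels are the matrix ids.  Merge height = half the average
    linkage distance; branch length = parent height - child height
    (zero-length internal branches occur when heights tie).
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 species")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    # working matrix over active cluster slots; merged clusters are retired
    work = np.array(dm.data, dtype=float)
    np.fill_diagonal(work, np.inf)
    nodes: list[dendropy.Node] = []
    sizes = [1] * n
    keys: list[tuple[str, ...]] = [(lab,) for lab in labels]
    heights = [0.0] * n
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(lab)
        nodes.append(node)
    active = list(range(n))

    for _ in range(n - 1):
        sub = work[np.ix_(active, active)]
        dmin = sub.min()
        ti, tj = np.nonzero(sub == dmin)
        pairs = [(active[a], active[b]) for a, b in zip(ti, tj) if a < b]
        # deterministic tie-break: smallest pooled sorted label tuple
        i, j = min(pairs, key=lambda p: tuple(sorted(keys[p[0]] + keys[p[1]])))
        h = dmin / 2.0
        parent = dendropy.Node()
        for child_id in (i, j):
            child = nodes[child_id]
            child.edge.length = h - heights[child_id]
            parent.add_child(child)
        # average-linkage update written into slot i; slot j retires
        ni, nj = sizes[i], sizes[j]
        merged_row = (ni * work[i, :] + nj * work[j, :]) / (ni + nj)
        work[i, :] = merged_row
        work[:, i] = merged_row
        work[i, i] = np.inf
        nodes[i] = parent
        sizes[i] = ni + nj
        keys[i] = tuple(sorted(keys[i] + keys[j]))
        heights[i] = h
        active.remove(j)

    root = nodes[active[0]]
    tree.seed_node = root
    tree.seed_node.edge.length = None
    return tree


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths agree within ``rel_tol``
    relative to the deepest tip (absolute for trees of zero depth)."""
    depths = []
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        depths.append(depth)
    if not depths:
        return True
    dmax = max(depths)
    tol = rel_tol * max(dmax, 1.0) if dmax == 0 else rel_tol * dmax
    return (dmax - min(depths)) <= tol


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    m = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            m[i, j] = m[j, i] = pdm.patristic_distance(ti, taxa[j])
    return DistanceMatrix(m, ids=labels)
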