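"""Synthetic trees, traits, nested pools and Red List assignments.

Emulates the inputs of a national bird Red List analysis so the whole
pipeline is testable without external datasets: a pure-birth (Yule)
phylogeny; presence/absence trait groups generated by thresholding
Brownian motion on the tree, blended with independent noise so a
signal parameter interpolates between phylogenetically clustered
(signal = 1) and random (signal = 0) trait structure; lognormal body
mass from Brownian motion; nested national → regional → local species
pools; and threat-category assignments that are either random, biased
toward a focal clade, or biased toward large-bodied species.

Default category sizes echo the relative sizes of the four threat
categories in a national bird fauna (NT : VU : EN : CR ≈ 95 : 65 :
35 : 21 out of 1763 species), scaled to the simulated pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .redlist_analysis import CATEGORIES, RedListAssignment, ScaleHierarchy
from .trait_space import (
    BINARY_SET,
    BIRD_TRAIT_SCHEMA,
    QUANTITATIVE,
    TraitSchema,
    TraitTable,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_traits",
    "assign_categories",
    "find_focal_clade",
    "build_hierarchy",
    "perturb_topology",
    "default_category_sizes",
    "simulate_dataset",
]

#: National-scale category richness used to scale default sizes
#: (NT, VU, EN, CR out of a 1763-species pool).
_REFERENCE_CATEGORY_COUNTS = {"NT": 95, "VU": 65, "EN": 35, "CR": 21}
_REFERENCE_POOL = 1763


def default_category_sizes(n_pool: int) -> dict[str, int]:
    """Category sizes proportional to a national bird fauna, >= 1 each."""
    return {
        cat: max(1, round(n_pool * c / _REFERENCE_POOL))
        for cat, c in _REFERENCE_CATEGORY_COUNTS.items()
    }


def _subseed(seed: int, tag: str) -> int:
    import hashlib

    key = f"{seed}|{tag}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Rooted binary tree from a pure-birth process.

    Time runs from the root split (two lineages) until the moment the
    (n+1)-th lineage would arise, so the expected tree height is
    sum_{k=2..n} 1 / (birth_rate * k).  Tips are labelled sp0001,
    sp0002, ... in tree traversal order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    leaves: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        leaves.append((root.new_child(), 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(len(leaves)))
        node, birth = leaves.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            leaves.append((node.new_child(), t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node, birth in leaves:
        node.edge.length = t - birth
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"sp{i:0{width}d}")
    return tree


def _brownian_columns(
    tree: dendropy.Tree, n_cols: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Independent Brownian realisations down the tree; tip values only."""
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_cols)}
    labels: list[str] = []
    tip_rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, math.sqrt(length), size=n_cols) if length > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            labels.append(node.taxon.label)
            tip_rows.append(values[id(node)])
    return labels, np.vstack(tip_rows)


def simulate_traits(
    tree: dendropy.Tree,
    schema: TraitSchema = BIRD_TRAIT_SCHEMA,
    signal: float = 0.8,
    seed: int = 0,
    mass_median: float = 35.0,
    mass_sdlog: float = 1.5,
) -> TraitTable:
    """Trait table with tunable phylogenetic signal.

    Each binary trait thresholds a Brownian realisation at its median
    across tips; each tip then keeps that value with probability
    ``signal`` and is otherwise replaced by an independent fair coin.
    Any species left with an all-zero binary group gets one uniformly
    chosen presence in that group (every species must use *some* state
    of each niche axis).  Body mass is lognormal around
    ``mass_median`` (in grams) with log-scale spread ``mass_sdlog``,
    inheriting tree structure from a Brownian realisation.
    """
    if not (0.0 <= signal <= 1.0):
        raise ValueError("signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_binary = sum(len(g.traits) for g in schema.groups if g.kind == BINARY_SET)
    n_quant = sum(len(g.traits) for g in schema.groups if g.kind == QUANTITATIVE)
    labels, z = _brownian_columns(tree, n_binary + n_quant, rng)
    n = len(labels)
    data = {}
    col = 0
    for g in schema.groups:
        if g.kind == BINARY_SET:
            block = np.zeros((n, len(g.traits)))
            for j, trait in enumerate(g.traits):
                zz = z[:, col]
                col += 1
                signal_trait = (zz > np.median(zz)).astype(float)
                coin = (rng.random(n) < 0.5).astype(float)
                keep = rng.random(n) < signal
                block[:, j] = np.where(keep, signal_trait, coin)
            empty = block.sum(axis=1) == 0
            for i in np.nonzero(empty)[0]:
                block[i, int(rng.integers(len(g.traits)))] = 1.0
            for j, trait in enumerate(g.traits):
                data[trait] = block[:, j]
        else:
            for trait in g.traits:
                zz = z[:, col]
                col += 1
                sd = zz.std()
                zstd = (zz - np.median(zz)) / sd if sd > 0 else np.zeros(n)
                data[trait] = mass_median * np.exp(mass_sdlog * zstd)
    frame = pd.DataFrame(data, index=labels)
    return TraitTable(frame, schema)


def find_focal_clade(
    tree: dendropy.Tree, min_size: int, seed: int = 0,
    pool: set[str] | None = None,
) -> frozenset[str]:
    """Smallest proper clade with at least ``min_size`` tips.

    If ``pool`` is given the tree is first restricted to it.  Among
    minimal eligible clades one is chosen uniformly at random.  Falls
    back to the full tip set if no proper clade is large enough.
    """
    if pool is not None:
        tip_labels = {l.taxon.label for l in tree.leaf_node_iter()}
        if set(pool) != tip_labels:
            tree = tree.extract_tree_with_taxa_labels(labels=set(pool))
    rng = np.random.default_rng(seed)
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    candidates: list[frozenset[str]] = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(tips) >= min_size:
            candidates.append(tips)
    if not candidates:
        return all_tips
    smallest = min(len(c) for c in candidates)
    minimal = sorted(
        (c for c in candidates if len(c) == smallest), key=lambda c: tuple(sorted(c))
    )
    return minimal[int(rng.integers(len(minimal)))]


def assign_categories(
    pool: Sequence[str] | set[str],
    sizes: Mapping[str, int],
    scheme: str = "random",
    w: float = 1.0,
    tree: dendropy.Tree | None = None,
    traits: TraitTable | None = None,
    seed: int = 0,
    name: str = "redlist",
    region: str | None = None,
) -> RedListAssignment:
    """Draw disjoint threat categories from a species pool.

    ``random``: uniform sampling without replacement.
    ``clade_biased``: tips inside a focal clade (the smallest clade
    holding at least ``max(sizes)`` tips of the pool) get sampling
    weight ``w`` >= 1, others weight 1; ``w = inf`` confines the draw
    to the clade.  ``trait_biased``: weight ``w`` for species with
    body mass above the pool median.
    """
    pool = sorted(set(pool))
    sizes = {c: int(sizes[c]) for c in CATEGORIES if sizes.get(c, 0) > 0}
    total = sum(sizes.values())
    if total > len(pool):
        raise ValueError(f"category sizes ({total}) exceed pool size ({len(pool)})")
    if w < 1:
        raise ValueError("bias strength w must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(pool)
    weights = np.ones(n)
    if scheme == "random":
        pass
    elif scheme == "clade_biased":
        if tree is None:
            raise ValueError("clade_biased scheme needs a tree")
        focal = find_focal_clade(
            tree, min_size=max(sizes.values()), seed=_subseed(seed, "focal"),
            pool=set(pool),
        )
        inside = np.array([sp in focal for sp in pool])
        if math.isinf(w):
            weights = np.where(inside, 1.0, 0.0)
            if inside.sum() < total:
                raise ValueError("focal clade smaller than total category sizes")
        else:
            weights = np.where(inside, w, 1.0)
    elif scheme == "trait_biased":
        if traits is None:
            raise ValueError("trait_biased scheme needs a trait table")
        mass = traits.data.loc[pool, "body_mass"].to_numpy()
        weights = np.where(mass > np.median(mass), w, 1.0)
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    drawn = rng.choice(n, size=total, replace=False, p=weights / weights.sum())
    mapping: dict[str, str] = {}
    pos = 0
    for cat in CATEGORIES:
        if cat not in sizes:
            continue
        for idx in drawn[pos:pos + sizes[cat]]:
            mapping[pool[idx]] = cat
        pos += sizes[cat]
    return RedListAssignment(name=name, categories=mapping, region=region)


def build_hierarchy(
    pool: Sequence[str] | set[str],
    n_regions: int = 6,
    region_size: int = 128,
    n_local: int = 8,
    local_size: int = 32,
    seed: int = 0,
) -> ScaleHierarchy:
    """Nested pools: regions sampled from the national pool, local
    units sampled from their region.  Regions may overlap each other;
    every local unit is strictly inside its parent region."""
    pool = sorted(set(pool))
    if region_size > len(pool):
        raise ValueError("region_size exceeds national pool")
    if local_size > region_size:
        raise ValueError("local_size exceeds region_size")
    rng = np.random.default_rng(seed)
    regions: dict[str, frozenset[str]] = {}
    local_units: dict[str, tuple[str, frozenset[str]]] = {}
    for r in range(1, n_regions + 1):
        rname = f"region{r}"
        rsp = sorted(rng.choice(len(pool), size=region_size, replace=False))
        rspecies = frozenset(pool[i] for i in rsp)
        regions[rname] = rspecies
        rlist = sorted(rspecies)
        for s in range(1, n_local + 1):
            lsp = rng.choice(len(rlist), size=local_size, replace=False)
            local_units[f"{rname}_site{s}"] = (
                rname,
                frozenset(rlist[i] for i in lsp),
            )
    return ScaleHierarchy(
        national=frozenset(pool), regions=regions, local_units=local_units
    )


def perturb_topology(tree: dendropy.Tree, n_moves: int, seed: int = 0) -> dendropy.Tree:
    """Copy of the tree after ``n_moves`` random nearest-neighbour
    interchanges (models topological uncertainty across a tree
    sample; branch lengths are carried along unchanged)."""
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for _ in range(n_moves):
        internal = [
            nd for nd in out.preorder_internal_node_iter()
            if nd.parent_node is not None and len(nd.child_nodes()) == 2
        ]
        if not internal:
            break
        node = internal[int(rng.integers(len(internal)))]
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if not siblings:
            continue
        sib = siblings[int(rng.integers(len(siblings)))]
        child = node.child_nodes()[int(rng.integers(2))]
        parent.remove_child(sib)
        node.remove_child(child)
        node.add_child(sib)
        parent.add_child(child)
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic dataset."""

    n_species: int = 256
    birth_rate: float = 1.0
    schema: TraitSchema = BIRD_TRAIT_SCHEMA
    trait_signal: float = 0.8
    mass_median: float = 35.0
    mass_sdlog: float = 1.5
    n_regions: int = 6
    region_size: int = 128
    n_local: int = 8
    local_size: int = 32
    scheme: str = "random"
    bias_strength: float = 1.0
    category_sizes: Mapping[str, int] | None = None  # None: scale national counts
    n_phylogenies: int = 100
    nni_moves: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trait_signal <= 1.0):
            raise ValueError("trait_signal must be in [0, 1]")
        if self.bias_strength < 1:
            raise ValueError("bias_strength must be >= 1")
        if self.region_size > self.n_species or self.local_size > self.region_size:
            raise ValueError("infeasible nesting sizes")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    phylogenies: list[dendropy.Tree]
    traits: TraitTable
    hierarchy: ScaleHierarchy
    assignments: list[RedListAssignment] = field(default_factory=list)

    def write(self, directory) -> None:
        from . import cli_io

        cli_io.write_dataset(self, directory)


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full, self-consistent synthetic dataset.

    Emits the true phylogeny, a sample of NNI-perturbed phylogenies
    (for the consensus step), traits, a national → regional → local
    hierarchy, and Red List assignments: one global and one national
    list drawn from the national pool plus one list per region drawn
    from that region's pool, all using the configured scheme.
    """
    cfg = config or SimulationConfig()
    tree = simulate_yule_tree(cfg.n_species, cfg.birth_rate, seed=_subseed(cfg.seed, "tree"))
    phylogenies = [
        perturb_topology(tree, cfg.nni_moves, seed=_subseed(cfg.seed, f"phylo{i}"))
        for i in range(cfg.n_phylogenies)
    ]
    traits = simulate_traits(
        tree, cfg.schema, signal=cfg.trait_signal, seed=_subseed(cfg.seed, "traits"),
        mass_median=cfg.mass_median, mass_sdlog=cfg.mass_sdlog,
    )
    pool = sorted(l.taxon.label for l in tree.leaf_node_iter())
    hierarchy = build_hierarchy(
        pool, cfg.n_regions, cfg.region_size, cfg.n_local, cfg.local_size,
        seed=_subseed(cfg.seed, "hierarchy"),
    )

    def _assign(list_name: str, list_pool, region=None) -> RedListAssignment:
        sizes = dict(cfg.category_sizes) if cfg.category_sizes else \
            default_category_sizes(len(list_pool))
        return assign_categories(
            list_pool, sizes, scheme=cfg.scheme, w=cfg.bias_strength,
            tree=tree, traits=traits, seed=_subseed(cfg.seed, f"assign|{list_name}"),
            name=list_name, region=region,
        )

    assignments = [_assign("global", pool), _assign("national", pool)]
    for rname in sorted(hierarchy.regions):
        assignments.append(
            _assign(f"redlist_{rname}", hierarchy.regions[rname], region=rname)
        )
    return SyntheticDataset(
        config=cfg, tree=tree, phylogenies=phylogenies, traits=traits,
        hierarchy=hierarchy, assignments=assignments,
    )
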