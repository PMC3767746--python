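import numpy as np
import pytest
from scipy import stats

from redlistdiv import (
    RedListAssignment,
    assign_categories,
    build_hierarchy,
    default_category_sizes,
    find_focal_clade,
    simulate_dataset,
    simulate_traits,
    simulate_yule_tree,
    validate_traits,
)
from redlistdiv.synthetic_data import SimulationConfig


class TestYule:
    def test_two_tips_form_an_equal_cherry(self):
        tree = simulate_yule_tree(2, seed=3)
        lengths = [l.edge.length for l in tree.leaf_node_iter()]
        assert len(lengths) == 2
        assert lengths[0] == pytest.approx(lengths[1])

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_binary_rooted_tree_shape(self, n):
        tree = simulate_yule_tree(n, seed=n)
        assert len(tree.leaf_nodes()) == n
        internal = list(tree.preorder_internal_node_iter())
        assert len(internal) == n - 1
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        assert len(edges) == 2 * n - 2

    def test_reproducible_by_seed(self):
        a = simulate_yule_tree(12, seed=5).as_string(schema="newick")
        b = simulate_yule_tree(12, seed=5).as_string(schema="newick")
        c = simulate_yule_tree(12, seed=6).as_string(schema="newick")
        assert a == b and a != c

    def test_mean_height_matches_pure_birth_expectation(self):
        """Tree height is a sum of exponential waiting times, with
        closed-form mean sum_{k=2..n} 1/(lambda k)."""
        n, lam, reps = 16, 1.0, 2000
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        var = sum(1.0 / (lam * k) ** 2 for k in range(2, n + 1))
        heights = np.empty(reps)
        for i in range(reps):
            tree = simulate_yule_tree(n, birth_rate=lam, seed=10_000 + i)
            leaf = next(tree.leaf_node_iter())
            h, node = 0.0, leaf
            while node.parent_node is not None:
                h += node.edge.length
                node = node.parent_node
            heights[i] = h
        se = np.sqrt(var / reps)
        assert abs(heights.mean() - expected) < 3 * se

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1)


class TestTraits:
    def test_output_always_passes_validation(self):
        for seed in range(5):
            tree = simulate_yule_tree(20, seed=seed)
            table = simulate_traits(tree, seed=seed)
            assert validate_traits(table).ok

    def test_signal_zero_traits_are_independent_of_the_tree(self):
        """Without signal, within-clade and between-clade trait
        similarity agree on average."""
        diffs = []
        for seed in range(60):
            tree = simulate_yule_tree(16, seed=seed)
            table = simulate_traits(tree, signal=0.0, seed=seed + 1)
            clade = sorted(find_focal_clade(tree, min_size=5, seed=seed))
            labels = list(table.species)
            inside = [l for l in labels if l in set(clade)]
            outside = [l for l in labels if l not in set(clade)]
            x = table.data.loc[:, table.data.columns != "body_mass"].to_numpy()
            ix = [labels.index(l) for l in inside]
            ox = [labels.index(l) for l in outside]
            within = np.mean([np.mean(x[a] == x[b]) for a in ix for b in ix if a < b])
            between = np.mean([np.mean(x[a] == x[b]) for a in ix for b in ox])
            diffs.append(within - between)
        assert abs(np.mean(diffs)) < 0.02

    def test_full_signal_sorts_traits_by_clade(self):
        """With signal = 1 on a two-clade tree with long stems, trait
        values are near-perfectly sorted by clade in most replicates."""
        import dendropy

        def cherry(labels):
            return "(" + ",".join(f"{l}:0.05" for l in labels) + ")"

        a = [f"a{i}" for i in range(8)]
        b = [f"b{i}" for i in range(8)]
        nwk = (f"(({cherry(a[:4])}:0.05,{cherry(a[4:])}:0.05):10,"
               f"({cherry(b[:4])}:0.05,{cherry(b[4:])}:0.05):10);")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        sorted_runs = 0
        for seed in range(30):
            table = simulate_traits(tree, signal=1.0, seed=seed)
            x = table.data.loc[:, table.data.columns != "body_mass"]
            inside = x.index.str.startswith("a")
            # a clade-sorted trait is near-constant within each clade
            per_trait = [
                min(x.iloc[list(inside), j].mean(), 1 - x.iloc[list(inside), j].mean())
                for j in range(x.shape[1])
            ]
            sorted_runs += np.mean(per_trait) < 0.1
        assert sorted_runs >= 20

    def test_mass_is_positive_with_requested_median(self):
        tree = simulate_yule_tree(64, seed=8)
        table = simulate_traits(tree, seed=9, mass_median=35.0)
        mass = table.data["body_mass"]
        assert (mass > 0).all()
        assert np.median(mass) == pytest.approx(35.0, rel=0.2)


class TestAssignments:
    def test_requested_sizes_are_honoured_and_disjoint(self):
        pool = [f"s{i:03d}" for i in range(100)]
        a = assign_categories(pool, {"NT": 5, "VU": 5, "EN": 3, "CR": 2}, seed=3)
        counts = {c: len(a.species_in(c)) for c in ("NT", "VU", "EN", "CR")}
        assert counts == {"NT": 5, "VU": 5, "EN": 3, "CR": 2}
        assert len(a.categories) == 15  # no species in two categories

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            assign_categories(["a", "b"], {"NT": 3}, seed=0)

    def test_weight_one_clade_bias_is_indistinguishable_from_random(self):
        """Chi-square goodness of fit of inclusion counts: with w = 1
        every species is drawn equally often."""
        tree = simulate_yule_tree(20, seed=11)
        pool = sorted(l.taxon.label for l in tree.leaf_node_iter())
        counts = {sp: 0 for sp in pool}
        n_draws = 2000
        for i in range(n_draws):
            a = assign_categories(pool, {"NT": 4}, scheme="clade_biased", w=1.0,
                                  tree=tree, seed=50_000 + i)
            for sp in a.categories:
                counts[sp] += 1
        observed = np.array([counts[sp] for sp in pool])
        expected = np.full(len(pool), n_draws * 4 / len(pool))
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_infinite_bias_confines_categories_to_the_focal_clade(self):
        tree = simulate_yule_tree(32, seed=13)
        pool = sorted(l.taxon.label for l in tree.leaf_node_iter())
        a = assign_categories(pool, {"CR": 4}, scheme="clade_biased", w=np.inf,
                              tree=tree, seed=17)
        clade = None
        for node in tree.preorder_internal_node_iter():
            tips = {l.taxon.label for l in node.leaf_iter()}
            if set(a.categories) <= tips and node.parent_node is not None:
                clade = tips
                break
        assert clade is not None and len(clade) < len(pool)

    def test_strong_bias_enriches_the_heavy_half(self):
        tree = simulate_yule_tree(40, seed=21)
        table = simulate_traits(tree, seed=22)
        pool = list(table.species)
        heavy = set(
            table.data.index[table.data["body_mass"] > table.data["body_mass"].median()]
        )
        inside = 0
        for i in range(50):
            a = assign_categories(pool, {"VU": 6}, scheme="trait_biased", w=50.0,
                                  traits=table, seed=600 + i)
            inside += sum(sp in heavy for sp in a.categories)
        assert inside / (50 * 6) > 0.8


class TestHierarchy:
    def test_degenerate_single_unit_nesting_accepted(self):
        pool = [f"s{i}" for i in range(10)]
        h = build_hierarchy(pool, n_regions=1, region_size=10, n_local=1,
                            local_size=10, seed=1)
        assert h.regions["region1"] == frozenset(pool)
        assert h.local_units["region1_site1"][1] == frozenset(pool)

    def test_nesting_invariants_hold(self):
        pool = [f"s{i:03d}" for i in range(60)]
        h = build_hierarchy(pool, n_regions=3, region_size=30, n_local=2,
                            local_size=10, seed=2)
        for name, sp in h.regions.items():
            assert sp <= h.national and len(sp) == 30
        for name, (parent, sp) in h.local_units.items():
            assert sp <= h.regions[parent] and len(sp) == 10

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_hierarchy(["a", "b"], n_regions=1, region_size=5, n_local=1,
                            local_size=2)


class TestBundle:
    def test_default_category_sizes_scale_the_national_counts(self):
        sizes = default_category_sizes(1763)
        assert sizes == {"NT": 95, "VU": 65, "EN": 35, "CR": 21}
        small = default_category_sizes(64)
        assert all(v >= 1 for v in small.values())
        assert small["NT"] >= small["CR"]

    def test_dataset_is_self_consistent(self):
        cfg = SimulationConfig(n_species=40, n_regions=2, region_size=24,
                               n_local=2, local_size=12, n_phylogenies=5, seed=4)
        ds = simulate_dataset(cfg)
        labels = {l.taxon.label for l in ds.tree.leaf_node_iter()}
        assert ds.hierarchy.national == labels
        assert set(ds.traits.species) == labels
        assert len(ds.phylogenies) == 5
        for a in ds.assignments:
            assert set(a.categories) <= labels
            if a.region:
                assert set(a.categories) <= ds.hierarchy.regions[a.region]
        region_lists = [a for a in ds.assignments if a.region]
        assert len(region_lists) == 2
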