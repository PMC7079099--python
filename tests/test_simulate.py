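"""Coalescent simulator, degradation operators, bladj dating, tree quintet."""

import numpy as np
import pytest

from phylofidelity import (
    DegradationConfig,
    bladj_date,
    collapse_nodes,
    make_tree_set,
    patristic_distances,
    read_newick,
    rescale_to_root_age,
    simulate_coalescent_tree,
    write_newick,
)
from phylofidelity.tree import Phylogeny


class TestCoalescent:
    def test_determinism(self):
        a = simulate_coalescent_tree(20, 42)
        b = simulate_coalescent_tree(20, 42)
        assert write_newick(a) == write_newick(b)

    def test_ultrametric_bifurcating(self):
        t = simulate_coalescent_tree(30, 7)
        assert t.is_ultrametric()
        assert t.polytomy_count() == 0
        assert all(len(ch) in (0, 2) for ch in t.children)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_coalescent_tree(1, 0)

    def test_pair_tmrca_is_exponential_mean_one(self):
        # with two lineages the root age is Exponential(1)
        ages = [simulate_coalescent_tree(2, s).root_age() for s in range(3000)]
        se = np.std(ages, ddof=1) / np.sqrt(len(ages))
        assert abs(np.mean(ages) - 1.0) < 3 * se

    def test_tmrca_mean_matches_coalescent_expectation(self):
        # E[TMRCA] = 2 (1 - 1/n)
        n = 50
        ages = [simulate_coalescent_tree(n, s).root_age() for s in range(2000)]
        se = np.std(ages, ddof=1) / np.sqrt(len(ages))
        assert abs(np.mean(ages) - 2 * (1 - 1 / n)) < 3 * se


class TestRescale:
    def test_linear_scaling(self, toy_tree):
        scaled = rescale_to_root_age(toy_tree, 100.0)
        assert scaled.root_age() == pytest.approx(100.0)
        d = patristic_distances(scaled)
        assert d.get("A", "B") == pytest.approx(100.0)  # branch A:1 -> 50

    def test_identity_and_topology(self, toy_tree):
        same = rescale_to_root_age(toy_tree, toy_tree.root_age())
        assert np.allclose(
            patristic_distances(same).values, patristic_distances(toy_tree).values
        )
        assert np.array_equal(same.parent, toy_tree.parent)


class TestCollapse:
    def test_fraction_zero_is_identity(self):
        tree = simulate_coalescent_tree(20, 5)
        topo, ages = collapse_nodes(tree, 0.0)
        assert write_newick(topo) == write_newick(tree)
        assert len(ages) == 19  # root + 18 internal non-root

    def test_full_collapse_gives_star(self):
        tree = simulate_coalescent_tree(4, 1)
        frac = 0.99  # ceil(0.99 * 2) = both internal non-root nodes
        topo, _ = collapse_nodes(tree, frac, rule="random", seed=0)
        assert sum(1 for ch in topo.children if ch) == 1  # only the root remains
        assert sorted(topo.tip_labels) == sorted(tree.tip_labels)

    @pytest.mark.parametrize("rule", ["youngest-first", "random"])
    def test_polytomies_monotone_in_fraction(self, rule):
        tree = simulate_coalescent_tree(60, 9)
        counts = [
            collapse_nodes(tree, f, rule=rule, seed=3)[0].polytomy_count()
            for f in (0.0, 0.2, 0.5)
        ]
        assert counts[0] == 0
        assert counts == sorted(counts)

    def test_survivor_ages_preserved(self):
        tree = simulate_coalescent_tree(30, 2)
        topo, ages = collapse_nodes(tree, 0.3, rule="youngest-first")
        got = topo.node_ages()
        for i in range(topo.n_nodes):
            if topo.children[i]:
                assert got[i] == pytest.approx(ages[topo.labels[i]], abs=1e-9)


class TestBladj:
    def test_even_interpolation_chain(self):
        # root(10) -> X(undated) -> tip : X gets age 5
        chain = Phylogeny(
            np.array([-1, 0, 1]), np.full(3, np.nan), ["R", "X", "tip"]
        )
        out = bladj_date(chain, {"R": 10.0})
        assert out.node_ages()[1] == pytest.approx(5.0)

    def test_interpolation_below_fixed_internal(self):
        # root 12, X fixed 6, Y undated between X and a tip: Y = 3
        ch = Phylogeny(
            np.array([-1, 0, 1, 2]), np.full(4, np.nan), ["R", "X", "Y", "tip"]
        )
        out = bladj_date(ch, {"R": 12.0, "X": 6.0})
        assert out.node_ages()[2] == pytest.approx(3.0)

    def test_all_fixed_reproduces_input(self):
        tree = simulate_coalescent_tree(40, 11)
        topo, ages = collapse_nodes(tree, 0.0)
        redated = bladj_date(topo, ages)
        assert np.allclose(redated.blen[1:], tree.blen[1:], atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_partial_dating_properties(self, seed):
        """Fixed nodes keep their age exactly; branch lengths >= 0; output
        ultrametric."""
        tree = rescale_to_root_age(simulate_coalescent_tree(50, seed), 100.0)
        topo, ages = collapse_nodes(tree, 0.2, rule="random", seed=seed)
        rng = np.random.default_rng(seed)
        internal = [lab for lab in ages if lab != topo.labels[0]]
        keep = list(rng.choice(internal, size=len(internal) // 3, replace=False))
        fixed = {lab: ages[lab] for lab in keep}
        fixed[topo.labels[0]] = ages[topo.labels[0]]
        out = bladj_date(topo, fixed)
        assert out.is_ultrametric()
        assert np.all(out.blen[1:] >= -1e-12)
        got = out.node_ages()
        for i in range(out.n_nodes):
            if out.labels[i] in fixed:
                assert got[i] == pytest.approx(fixed[out.labels[i]], abs=1e-6)

    def test_inconsistent_ages_rejected(self):
        ch = Phylogeny(
            np.array([-1, 0, 1, 2]), np.full(4, np.nan), ["R", "X", "Y", "tip"]
        )
        with pytest.raises(ValueError, match="X"):
            bladj_date(ch, {"R": 5.0, "X": 9.0})

    def test_missing_root_age_rejected(self):
        ch = Phylogeny(np.array([-1, 0, 1]), np.full(3, np.nan), ["R", "X", "tip"])
        with pytest.raises(ValueError, match="root"):
            bladj_date(ch, {"X": 1.0})


class TestTreeSet:
    def test_common_tip_set(self, small_quintet):
        ts = small_quintet
        expect = int(np.ceil(80 * 0.95))
        assert len(ts.common_tips) == expect
        for tree in ts.trees.values():
            assert sorted(tree.tip_labels) == list(ts.common_tips)

    def test_random_tree_root_age(self, small_quintet):
        ts = small_quintet
        mean_degraded = np.mean([t.root_age() for t in ts.degraded.values()])
        assert ts.tree_random.root_age() == pytest.approx(mean_degraded, rel=1e-6)

    def test_degraded_have_more_polytomies(self, small_quintet):
        ts = small_quintet
        base = ts.tree_purpose.polytomy_count()
        for name, tree in ts.degraded.items():
            assert tree.polytomy_count() >= base, name

    def test_determinism(self):
        a = make_tree_set(30, 50.0, seed=77)
        b = make_tree_set(30, 50.0, seed=77)
        for name in a.trees:
            assert write_newick(a.trees[name]) == write_newick(b.trees[name])

    def test_zero_degradation_identity_limit(self):
        ts = make_tree_set(30, 50.0, DegradationConfig.zero(), seed=5)
        d0 = patristic_distances(ts.tree_purpose)
        for name, tree in ts.degraded.items():
            d = patristic_distances(tree)
            idx = d.index_of(d0.labels)
            assert np.allclose(d.values[np.ix_(idx, idx)], d0.values, atol=1e-6), name

    def test_ultrametric_everywhere(self, small_quintet):
        for name, tree in small_quintet.trees.items():
            assert tree.is_ultrametric(1e-6), name
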