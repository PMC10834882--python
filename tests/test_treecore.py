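"""Tree model: traversals, signatures, LCA, depths, and transforms."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from phylopipe import (NodeLookupError, TreeError, clade_signature, collapse,
                       lca, node_depths, parse_newick, prune,
                       reroot_on_branch, rotate, traverse, write_newick,
                       yule_tree, SynthOptions)
from phylopipe.layout import visible_terminals


def clade_set(tree):
    return {clade_signature(n).leaves for n in traverse(tree, "preorder")}


def total_length(tree):
    return sum(n.length or 0.0 for n in traverse(tree, "preorder"))


class TestTraverse:
    def test_single_leaf_identity(self):
        tree = parse_newick("A;").trees[0]
        assert len(traverse(tree, "preorder")) == 1
        assert len(traverse(tree, "postorder")) == 1

    def test_node_count_three_leaf(self, bare_topology):
        assert len(traverse(bare_topology, "preorder")) == 5
        assert len(traverse(bare_topology, "postorder")) == 5

    def test_postorder_children_before_parents(self, three_leaf):
        order = traverse(three_leaf, "postorder")
        position = {node: i for i, node in enumerate(order)}
        for node in order:
            for child in node.children:
                assert position[child] < position[node]

    def test_orders_agree_as_sets_on_random_tree(self, random_tree_factory):
        tree = random_tree_factory(50, seed=7)
        pre = traverse(tree, "preorder")
        post = traverse(tree, "postorder")
        assert len(pre) == len(post) == len(set(pre))
        assert set(pre) == set(post)
        # edges = nodes - 1 in any rooted tree
        edges = sum(len(n.children) for n in pre)
        assert edges == len(pre) - 1


class TestSignaturesAndLca:
    def test_signatures(self, bare_topology):
        keys = {clade_signature(n).leaves
                for n in traverse(bare_topology, "preorder")}
        assert frozenset({"A"}) in keys
        assert frozenset({"A", "B"}) in keys
        assert frozenset({"A", "B", "C"}) in keys

    def test_lca_cases(self, bare_topology):
        assert lca(bare_topology, {"A"}).name == "A"
        assert clade_signature(lca(bare_topology, {"A", "B"})).leaves == \
            frozenset({"A", "B"})
        # brute force: deepest node containing {A, C} is the root
        assert lca(bare_topology, {"A", "C"}) is bare_topology.root

    def test_unknown_name_raises(self, bare_topology):
        with pytest.raises(NodeLookupError):
            lca(bare_topology, {"A", "Z"})


class TestDepths:
    def test_simple_depths(self):
        tree = parse_newick("(A:1,B:2);").trees[0]
        depths, height = node_depths(tree)
        by_name = {n.name: d for n, d in depths.items() if n.is_leaf}
        assert by_name == {"A": 1.0, "B": 2.0}
        assert height == 2.0

    def test_internal_depth_and_height(self, three_leaf):
        depths, height = node_depths(three_leaf)
        assert height == 2.0
        internal = lca(three_leaf, {"A", "B"})
        assert depths[internal] == 1.0

    def test_ultrametric_synthetic_leaves_equal(self):
        tree = yule_tree(SynthOptions(n_leaves=20, seed=5))
        depths, height = node_depths(tree)
        for node, depth in depths.items():
            if node.is_leaf:
                assert abs(depth - height) < 1e-9


class TestReroot:
    def test_hand_computed_example(self, three_leaf):
        rerooted = reroot_on_branch(three_leaf, {"C"}, fraction=0.5)
        children = rerooted.root.children
        assert len(children) == 2
        first, second = children
        assert first.name == "C" and first.length == pytest.approx(1.0)
        assert clade_signature(second).leaves == frozenset({"A", "B"})
        assert second.length == pytest.approx(2.0)

    def test_total_length_conserved(self, random_tree_factory):
        for seed in range(5):
            tree = random_tree_factory(12, seed=seed)
            before = total_length(tree)
            rerooted = reroot_on_branch(tree, {"L0"}, fraction=0.3)
            assert total_length(rerooted) == pytest.approx(before, abs=1e-9)
            assert sorted(rerooted.leaf_names()) == sorted(tree.leaf_names())

    def test_reroot_back_restores_clades(self, three_leaf):
        once = reroot_on_branch(three_leaf, {"C"}, fraction=0.5)
        # the original root edge is now the branch above the {A,B} clade
        back = reroot_on_branch(once, {"A", "B"}, fraction=0.5)
        assert clade_set(back) == clade_set(three_leaf)

    def test_selector_at_root_is_error(self, three_leaf):
        with pytest.raises(TreeError):
            reroot_on_branch(three_leaf, {"A", "B", "C"}, 0.5)


class TestPrune:
    def test_prune_collapses_root(self, three_leaf):
        assert write_newick(prune(three_leaf, {"C"})) == "(A:1,B:1);"

    def test_length_additivity(self):
        tree = parse_newick("((A:1,B:1):2,C:3);").trees[0]
        pruned = prune(tree, {"B"})
        a = lca(pruned, {"A"})
        assert a.length == pytest.approx(3.0)

    def test_leaf_set_is_difference(self, random_tree_factory):
        tree = random_tree_factory(20, seed=2)
        target = clade_signature(tree.root.children[0]).leaves
        pruned = prune(tree, target)
        assert set(pruned.leaf_names()) == set(tree.leaf_names()) - target

    def test_disjoint_prunes_commute(self, random_tree_factory):
        tree = random_tree_factory(20, seed=9)
        first = clade_signature(lca(tree, {"L0"})).leaves
        second = clade_signature(lca(tree, {"L11"})).leaves
        assert not (first & second)
        ab = prune(prune(tree, first), second)
        ba = prune(prune(tree, second), first)
        assert clade_set(ab) == clade_set(ba)


class TestCollapseRotate:
    def test_collapse_reduces_terminals(self, bare_topology):
        collapsed = collapse(bare_topology, {"A", "B"}, True)
        assert len(visible_terminals(collapsed)) == 2

    def test_collapse_involution(self, bare_topology):
        roundtrip = collapse(collapse(bare_topology, {"A", "B"}, True),
                             {"A", "B"}, False)
        assert write_newick(roundtrip) == write_newick(bare_topology)
        assert not lca(roundtrip, {"A", "B"}).collapsed

    def test_nested_collapse_inert_but_retained(self):
        tree = parse_newick("(((A,B),C),D);").trees[0]
        tree = collapse(tree, {"A", "B"}, True)
        tree = collapse(tree, {"A", "B", "C"}, True)
        # the outer collapse hides the inner one, whose flag persists
        terminals = visible_terminals(tree)
        assert len(terminals) == 2
        assert lca(tree, {"A", "B"}).collapsed

    def test_collapse_leaf_is_error(self, bare_topology):
        with pytest.raises(TreeError):
            collapse(bare_topology, {"A"}, True)

    def test_rotate_reverses_and_involutes(self, bare_topology):
        rotated = rotate(bare_topology, {"A", "B", "C"})
        assert [t.name for t in visible_terminals(rotated)] == ["C", "A", "B"]
        twice = rotate(rotated, {"A", "B", "C"})
        assert write_newick(twice) == write_newick(bare_topology)

    def test_rotate_preserves_clades(self, random_tree_factory):
        tree = random_tree_factory(15, seed=4)
        rotated = rotate(tree, set(tree.leaf_names()))
        assert clade_set(rotated) == clade_set(tree)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), fraction=st.floats(0.0, 1.0))
def test_reroot_conserves_length_and_leaves(seed, fraction):
    """Property: rerooting anywhere conserves branch length and taxa."""
    from conftest import random_rooted_tree
    import numpy as np
    tree = random_rooted_tree(np.random.default_rng(seed),
                              [f"X{i}" for i in range(8)])
    rerooted = reroot_on_branch(tree, {"X5"}, fraction)
    assert total_length(rerooted) == pytest.approx(total_length(tree),
                                                   abs=1e-9)
    assert sorted(rerooted.leaf_names()) == sorted(tree.leaf_names())
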