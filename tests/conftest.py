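import numpy as np
import pytest

from phylopipe import (SynthOptions, Tree, TreeCollection, TreeNode,
                       parse_newick, posterior_sample, yule_tree)


@pytest.fixture
def three_leaf():
    """The canonical ((A,B),C) tree with clock-like lengths."""
    return parse_newick("((A:1,B:1):1,C:2);").trees[0]


@pytest.fixture
def bare_topology():
    return parse_newick("((A,B),C);").trees[0]


def random_rooted_tree(rng: np.random.Generator, names) -> Tree:
    """Uniform-ish random rooted binary tree by sequential joining."""
    nodes = []
    for name in names:
        leaf = TreeNode({"Name": name})
        leaf.length = float(rng.uniform(0.1, 2.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return Tree(root)


@pytest.fixture
def random_tree_factory():
    def factory(n_leaves: int, seed: int) -> Tree:
        rng = np.random.default_rng(seed)
        return random_rooted_tree(rng, [f"L{i}" for i in range(n_leaves)])
    return factory


@pytest.fixture(scope="session")
def small_posterior():
    """A 6-taxon, 200-tree synthetic posterior with its true base tree."""
    options = SynthOptions(n_leaves=6, n_trees=200, age_jitter_sd=0.05,
                           topology_swap_prob=0.05, seed=11)
    base = yule_tree(options)
    return base, posterior_sample(base, options)
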