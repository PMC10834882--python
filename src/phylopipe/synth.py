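"""Seeded synthetic chronograms and posterior-like tree collections.

The generator emulates the shape of Bayesian molecular-clock output —
a file of many near-ultrametric trees over a shared taxon set, such as
a PhyloBayes posterior sample (1000 trees over 42 taxa in the worked
example this package reproduces):

* :func:`yule_tree` draws one exactly ultrametric tree from a
  pure-birth (Yule) process, recording every node's true age in the
  ``TrueAge`` attribute;
* :func:`posterior_sample` produces jittered replicates of that base
  tree: each internal node age is perturbed by mean-one lognormal
  noise (re-sorted so parents stay older than children) and, with a
  configurable probability, a nearest-neighbour-interchange move
  shuffles the topology — mimicking posterior uncertainty in both node
  times and topology.

All output is a deterministic function of the seed. What the generator
does *not* emulate: correlated rate variation, fossil calibrations, or
the autocorrelation structure of a real MCMC chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .io import write_newick, write_nexus
from .tree import Tree, TreeCollection, TreeNode, traverse

__all__ = ["SynthOptions", "yule_tree", "posterior_sample", "write_fixture"]


@dataclass
class SynthOptions:
    """Generator parameters.

    n_leaves / n_trees default to the worked example's file shape
    (42 taxa, 1000 posterior trees). ``age_jitter_sd`` is the relative
    (lognormal sigma) spread of node ages across replicates — 0.05,
    i.e. ~5%, is typical of a well-converged node-dating posterior —
    and ``topology_swap_prob`` is the chance a replicate undergoes one
    NNI move (0.05: most posterior topology mass on the consensus).
    """

    n_leaves: int = 42
    birth_rate: float = 1.0
    n_trees: int = 1000
    age_jitter_sd: float = 0.05
    topology_swap_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.age_jitter_sd < 0:
            raise ValueError("age_jitter_sd must be >= 0")
        if not 0.0 <= self.topology_swap_prob <= 1.0:
            raise ValueError("topology_swap_prob must be in [0, 1]")


def yule_tree(options: SynthOptions) -> Tree:
    """One ultrametric pure-birth tree with true node ages recorded.

    Two lineages start at time 0; while fewer than ``n_leaves``
    lineages exist, an exponential waiting time with rate
    ``k * birth_rate`` elapses and a uniformly chosen lineage splits.
    The tree is cut at the time the next split *would* occur, so every
    tip has positive terminal branch length. Leaves are named
    ``T1..Tn`` in plot order; internal nodes carry ``TrueAge`` (time
    before the tips).
    """
    rng = np.random.default_rng(options.seed)
    root = TreeNode()
    birth_time: Dict[int, float] = {id(root): 0.0}
    tips: List[TreeNode] = [root.add_child(TreeNode()),
                            root.add_child(TreeNode())]
    now = 0.0
    for tip in tips:
        birth_time[id(tip)] = now
    while True:
        k = len(tips)
        now += float(rng.exponential(1.0 / (k * options.birth_rate)))
        if k == options.n_leaves:
            break
        index = int(rng.integers(k))
        parent = tips.pop(index)
        birth_time[id(parent)] = now
        left, right = TreeNode(), TreeNode()
        parent.add_child(left)
        parent.add_child(right)
        birth_time[id(left)] = now
        birth_time[id(right)] = now
        tips.insert(index, left)
        tips.append(right)
    height = now
    tree = Tree(root)
    counter = 0
    for node in traverse(tree, "preorder"):
        time = birth_time[id(node)] if node.children else height
        if node.parent is not None:
            node.length = time - birth_time[id(node.parent)]
        if node.children:
            node.attributes["TrueAge"] = height - time
        else:
            counter += 1
            node.name = f"T{counter}"
    return tree


def _internal_nodes(tree: Tree) -> List[TreeNode]:
    return [n for n in traverse(tree, "preorder") if n.children]


def _ages_from_lengths(tree: Tree) -> Dict[int, float]:
    from .tree import node_depths
    depths, height = node_depths(tree)
    return {id(n): height - d for n, d in depths.items()}


def _set_lengths_from_ages(tree: Tree, age: Dict[int, float]) -> None:
    for node in traverse(tree, "preorder"):
        if node.parent is None:
            continue
        node_age = age[id(node)] if node.children else 0.0
        node.length = max(0.0, age[id(node.parent)] - node_age)


def _nni(tree: Tree, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange at a random internal edge."""
    candidates = [n for n in _internal_nodes(tree)
                  if n.parent is not None and len(n.parent.children) >= 2]
    if not candidates:
        return
    child = candidates[int(rng.integers(len(candidates)))]
    parent = child.parent
    siblings = [c for c in parent.children if c is not child]
    sibling = siblings[int(rng.integers(len(siblings)))]
    grandchild = child.children[int(rng.integers(len(child.children)))]
    # swap grandchild and sibling
    ci = child.children.index(grandchild)
    pi = parent.children.index(sibling)
    child.children[ci], parent.children[pi] = sibling, grandchild
    sibling.parent, grandchild.parent = child, parent


def posterior_sample(base: Tree, options: SynthOptions) -> TreeCollection:
    """Jittered replicates of ``base`` emulating a posterior tree sample.

    Per replicate: (1) with probability ``topology_swap_prob`` one NNI
    move; (2) every node age multiplied by a tree-wide mean-one
    lognormal factor (sigma = ``age_jitter_sd``) — the signature of
    clock-rate uncertainty, which scales the whole chronogram — then
    clamped from the leaves upward so an NNI cannot leave a child older
    than its parent; (3) branch lengths rebuilt from the new ages (tips
    at age 0). The tree-wide factor keeps per-node sampled ages
    unbiased (their mean recovers the true age) while preserving the
    parent-older-than-child ordering exactly.
    """
    rng = np.random.default_rng(options.seed)
    sigma = options.age_jitter_sd
    mu = -0.5 * sigma * sigma
    replicates: List[Tree] = []
    for _ in range(options.n_trees):
        tree = base.copy()
        if options.topology_swap_prob > 0 and (
                rng.random() < options.topology_swap_prob):
            _nni(tree, rng)
        internals = _internal_nodes(tree)
        ages = _ages_from_lengths(tree)
        base_ages = np.array([ages[id(n)] for n in internals])
        if sigma > 0:
            factor = float(rng.lognormal(mean=mu, sigma=sigma))
            new_ages = base_ages * factor
        else:
            new_ages = base_ages
        for node, value in zip(internals, new_ages):
            ages[id(node)] = float(value)
        # clamp upward (an NNI can place an older clade under a younger
        # node; zero-length branches are allowed)
        for node in traverse(tree, "postorder"):
            if node.children:
                oldest_child = max(
                    ages[id(c)] if c.children else 0.0
                    for c in node.children)
                ages[id(node)] = max(ages[id(node)], oldest_child)
        _set_lengths_from_ages(tree, ages)
        replicates.append(tree)
    return TreeCollection(replicates)


def write_fixture(collection: TreeCollection, path: str,
                  format: str = "nexus") -> None:
    """Write a collection as a Newick (one tree per line) or NEXUS file.

    The NEXUS variant includes a generated TRANSLATE table.
    """
    if format == "newick":
        text = "\n".join(write_newick(tree) for tree in collection.trees) + "\n"
    elif format == "nexus":
        if collection.translate is None:
            taxa = collection.trees[0].leaf_names()
            collection = TreeCollection(
                collection.trees,
                translate={str(i + 1): name for i, name in enumerate(taxa)})
        text = write_nexus(collection)
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(text)
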