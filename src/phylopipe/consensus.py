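"""Consensus trees: reduce a posterior sample to a single summary tree.

Implements greedy consensus (clades added in frequency order while they
remain pairwise compatible) and strict-majority-rule consensus, with
optional burn-in and uniform subsampling of the input collection.
Consensus operates on rooted clades — clock trees are rooted — so
compatibility is the rooted criterion: two clades are compatible iff
one contains the other or they are disjoint.

Every consensus node is annotated with ``Support`` (the fraction of
retained trees containing the clade) and ``Length`` (the mean — or,
optionally, median — branch length over the trees containing it).

Tie-breaking between equal-frequency clades is deterministic (higher
count first, then smaller clade, then lexicographic canonical key) so
that re-running a pipeline is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional

import numpy as np

from .tree import (Tree, TreeCollection, TreeError, TreeNode, UNIT_SEP,
                   clade_signature, node_depths, traverse)

__all__ = [
    "ConsensusOptions",
    "CladeTable",
    "CladeEntry",
    "retained_trees",
    "clade_frequencies",
    "greedy_consensus",
    "majority_consensus",
    "consensus",
]

_EPS = 1e-9


@dataclass
class ConsensusOptions:
    """Parameters of the consensus Transformer stage.

    method
        ``greedy`` (default), ``majority``, or ``pick_index``.
    burn_in_fraction
        Fraction of initial trees discarded before summarising.
    sample_fraction
        Fraction of the post-burn-in trees kept, sampled uniformly
        without replacement (``seed`` drives the draw); order preserved.
    threshold
        Majority threshold; clades with frequency strictly above it are
        kept (0.5 = strict majority rule).
    index
        Which retained tree to pick for ``pick_index``.
    length_summary
        ``mean`` (default) or ``median`` branch-length summarisation.
    """

    method: str = "greedy"
    burn_in_fraction: float = 0.0
    sample_fraction: float = 1.0
    threshold: float = 0.5
    index: int = 0
    seed: int = 0
    length_summary: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.method == "majority" and self.threshold < 0.5:
            raise ValueError("majority threshold must be >= 0.5")
        if self.method not in ("greedy", "majority", "pick_index"):
            raise ValueError(f"unknown consensus method {self.method!r}")


@dataclass
class CladeEntry:
    leaves: FrozenSet[str]
    count: int = 0
    lengths: List[float] = field(default_factory=list)
    depth_sum: float = 0.0

    @property
    def size(self) -> int:
        return len(self.leaves)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths)) if self.lengths else 0.0

    @property
    def median_length(self) -> float:
        return float(np.median(self.lengths)) if self.lengths else 0.0

    @property
    def mean_depth(self) -> float:
        return self.depth_sum / self.count if self.count else 0.0


@dataclass
class CladeTable:
    """Clade -> frequency/branch-length accumulator over a tree sample."""

    entries: Dict[str, CladeEntry]
    n_trees: int


def _check_shared_leaves(trees: List[Tree]) -> FrozenSet[str]:
    reference = frozenset(trees[0].leaf_names())
    for tree in trees[1:]:
        leaves = frozenset(tree.leaf_names())
        if leaves != reference:
            diff = sorted(reference.symmetric_difference(leaves))
            raise TreeError(
                f"trees do not share a leaf set; symmetric difference: {diff}")
    return reference


def retained_trees(collection: TreeCollection,
                   options: ConsensusOptions) -> List[Tree]:
    """Apply burn-in then uniform subsampling; original order preserved."""
    trees = list(collection.trees)
    _check_shared_leaves(trees)
    n = len(trees)
    start = math.floor(options.burn_in_fraction * n)
    kept = trees[start:]
    k = math.floor(options.sample_fraction * len(kept))
    if k < 1:
        raise TreeError("burn-in and subsampling left no trees")
    if k < len(kept):
        rng = np.random.default_rng(options.seed)
        idx = np.sort(rng.choice(len(kept), size=k, replace=False))
        kept = [kept[i] for i in idx]
    return kept


def clade_frequencies(trees: List[Tree]) -> CladeTable:
    """Count every clade (leaves included) across ``trees``.

    For each clade the branch lengths and node depths are accumulated
    over the trees that contain it.
    """
    if not trees:
        raise TreeError("no trees to summarise")
    _check_shared_leaves(trees)
    entries: Dict[str, CladeEntry] = {}
    for tree in trees:
        depths, _ = node_depths(tree)
        signatures: Dict[TreeNode, FrozenSet[str]] = {}
        for node in traverse(tree, "postorder"):
            if node.is_leaf:
                signatures[node] = frozenset([node.name])
            else:
                merged: set = set()
                for child in node.children:
                    merged |= signatures[child]
                signatures[node] = frozenset(merged)
            leaves = signatures[node]
            key = UNIT_SEP.join(sorted(leaves))
            entry = entries.get(key)
            if entry is None:
                entry = entries[key] = CladeEntry(leaves)
            entry.count += 1
            if node.length is not None:
                entry.lengths.append(node.length)
            entry.depth_sum += depths[node]
    return CladeTable(entries, len(trees))


def _ordered_clades(table: CladeTable) -> List[str]:
    """Frequency order with the deterministic tie-break."""
    return sorted(table.entries,
                  key=lambda k: (-table.entries[k].count,
                                 table.entries[k].size, k))


def _compatible(a: FrozenSet[str], b: FrozenSet[str]) -> bool:
    return a <= b or b <= a or not (a & b)


def _build_from_clades(accepted: List[str], table: CladeTable,
                       length_summary: str) -> Tree:
    """Nest a set of pairwise-compatible rooted clades into a tree."""
    n_trees = table.n_trees
    by_size = sorted(accepted, key=lambda k: (table.entries[k].size, k))
    nodes: Dict[str, TreeNode] = {}
    for key in by_size:
        entry = table.entries[key]
        node = TreeNode()
        if entry.size == 1:
            node.attributes["Name"] = next(iter(entry.leaves))
        node.attributes["Support"] = entry.count / n_trees
        if entry.lengths:
            node.length = (entry.median_length
                           if length_summary == "median"
                           else entry.mean_length)
        nodes[key] = node
    # attach each clade to its smallest accepted strict superset
    root_key = max(by_size, key=lambda k: table.entries[k].size)
    for key in by_size:
        if key == root_key:
            continue
        leaves = table.entries[key].leaves
        parent_key = None
        for candidate in by_size:
            if candidate == key:
                continue
            cand_leaves = table.entries[candidate].leaves
            if leaves < cand_leaves:
                if parent_key is None or (table.entries[candidate].size
                                          < table.entries[parent_key].size):
                    parent_key = candidate
        nodes[parent_key].add_child(nodes[key])
    root = nodes[root_key]
    root.length = None  # a root has no subtending branch
    _sort_children(root)
    return Tree(root)


def _sort_children(node: TreeNode) -> None:
    node.children.sort(key=lambda c: UNIT_SEP.join(
        sorted(clade_signature(c).leaves)))
    for child in node.children:
        _sort_children(child)


def greedy_consensus(trees: List[Tree],
                     length_summary: str = "mean") -> Tree:
    """Greedy consensus: accept clades in frequency order while compatible.

    Clades are visited in decreasing count (ties: smaller clade first,
    then lexicographic canonical key) and accepted iff compatible with
    everything accepted so far. Always yields a fully specified rooted
    tree containing every majority clade.
    """
    table = clade_frequencies(trees)
    accepted: List[str] = []
    accepted_leaves: List[FrozenSet[str]] = []
    for key in _ordered_clades(table):
        leaves = table.entries[key].leaves
        if all(_compatible(leaves, other) for other in accepted_leaves):
            accepted.append(key)
            accepted_leaves.append(leaves)
    return _build_from_clades(accepted, table, length_summary)


def majority_consensus(trees: List[Tree], threshold: float = 0.5,
                       length_summary: str = "mean") -> Tree:
    """Majority-rule consensus: keep clades with frequency > threshold.

    The comparison is strict (a clade in exactly half the trees is not
    a majority clade), which is what makes accepted clades mutually
    compatible by the pigeonhole principle — no compatibility filtering
    is needed. Leaf clades and the full leaf set always qualify.
    """
    if threshold < 0.5:
        raise ValueError("majority threshold must be >= 0.5")
    table = clade_frequencies(trees)
    cutoff = threshold * table.n_trees + _EPS
    accepted = [key for key in _ordered_clades(table)
                if table.entries[key].count > cutoff]
    return _build_from_clades(accepted, table, length_summary)


def consensus(collection: TreeCollection,
              options: Optional[ConsensusOptions] = None) -> Tree:
    """Run the full Transformer stage: retain, then reduce to one tree."""
    options = options or ConsensusOptions()
    kept = retained_trees(collection, options)
    if options.method == "pick_index":
        if not 0 <= options.index < len(kept):
            raise TreeError(
                f"pick_index {options.index} out of range (retained "
                f"{len(kept)} trees)")
        return kept[options.index].copy()
    if options.method == "majority":
        return majority_consensus(kept, options.threshold,
                                  options.length_summary)
    return greedy_consensus(kept, options.length_summary)
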