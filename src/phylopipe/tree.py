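"""Attributed rooted-tree model and structural editing operations.

Every node carries an open-ended attribute map (name -> text or number).
A handful of attribute names are conventional: ``Name`` (taxon label,
required on leaves), ``Length`` (branch length subtending the node, in
whatever units the tree uses — time for clock trees) and ``Support``
(clade support proportion). Child order is significant: it is preserved
exactly as parsed and drives plot layout; :func:`rotate` is the only
operation that reorders children.

Node selectors throughout this package are *sets of leaf names* resolved
to the last common ancestor, so that a serialized pipeline can be
re-applied to a different tree file where node indices would be
meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Union

__all__ = [
    "AttrValue",
    "TreeNode",
    "Tree",
    "TreeCollection",
    "CladeSignature",
    "TreeError",
    "MalformedTreeError",
    "NodeLookupError",
    "UNIT_SEP",
    "traverse",
    "clade_signature",
    "canonical_key",
    "lca",
    "node_depths",
    "reroot_on_branch",
    "prune",
    "collapse",
    "rotate",
]

#: Attribute values are plain text or (finite) numbers; the Python type
#: encodes which of the two kinds a value is.
AttrValue = Union[str, float]

#: Reserved separator joining sorted leaf names into a canonical clade key.
UNIT_SEP = "\x1f"


class TreeError(Exception):
    """Base class for tree-model errors."""


class MalformedTreeError(TreeError):
    """The tree violates a structural invariant (e.g. unnamed leaf)."""


class NodeLookupError(TreeError, KeyError):
    """A node selector referenced a leaf name absent from the tree."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return Exception.__str__(self)


class TreeNode:
    """A node of a rooted tree with an attribute map and ordered children."""

    __slots__ = ("attributes", "children", "parent", "collapsed")

    def __init__(
        self,
        attributes: Optional[Dict[str, AttrValue]] = None,
        children: Iterable["TreeNode"] = (),
        collapsed: bool = False,
    ) -> None:
        self.attributes: Dict[str, AttrValue] = dict(attributes or {})
        self.children: List[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.collapsed = collapsed
        for child in children:
            self.add_child(child)

    # -- structure ---------------------------------------------------
    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "TreeNode") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    # -- conventional attributes -------------------------------------
    @property
    def name(self) -> Optional[str]:
        value = self.attributes.get("Name")
        return None if value is None else str(value)

    @name.setter
    def name(self, value: str) -> None:
        self.attributes["Name"] = value

    @property
    def length(self) -> Optional[float]:
        value = self.attributes.get("Length")
        return None if value is None else float(value)

    @length.setter
    def length(self, value: Optional[float]) -> None:
        if value is None:
            self.attributes.pop("Length", None)
        else:
            if not math.isfinite(value) or value < 0:
                raise MalformedTreeError(
                    f"branch length must be finite and >= 0, got {value!r}"
                )
            self.attributes["Length"] = float(value)

    def copy(self) -> "TreeNode":
        """Deep copy of this node's subtree (parent pointer not copied)."""
        clone = TreeNode(dict(self.attributes), collapsed=self.collapsed)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:
        label = self.name or f"<{len(self.children)} children>"
        return f"TreeNode({label!r})"


@dataclass
class Tree:
    """A rooted tree; leaf names must be unique within the tree."""

    root: TreeNode

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def leaves(self) -> List[TreeNode]:
        return [n for n in traverse(self, "preorder") if n.is_leaf]

    def leaf_names(self) -> List[str]:
        names = []
        for leaf in self.leaves():
            if leaf.name is None:
                raise MalformedTreeError("leaf without a Name attribute")
            names.append(leaf.name)
        return names

    def validate(self) -> None:
        """Check structural invariants; raise :class:`MalformedTreeError`."""
        names = self.leaf_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MalformedTreeError(f"duplicate leaf names: {dupes}")
        for node in traverse(self, "preorder"):
            length = node.attributes.get("Length")
            if length is not None:
                length = float(length)
                if not math.isfinite(length) or length < 0:
                    raise MalformedTreeError(
                        f"invalid branch length {length!r}"
                    )


@dataclass
class TreeCollection:
    """An ordered list of trees read from one file.

    ``translate`` is the optional NEXUS token -> taxon-name table the
    trees were decoded with (kept so it can be re-emitted on write).
    """

    trees: List[Tree]
    translate: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("a TreeCollection must contain at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)


@dataclass(frozen=True)
class CladeSignature:
    """The descendant leaf set of a node, with a canonical string key.

    Two nodes (possibly in different trees) match iff their canonical
    keys are equal; the key joins the sorted leaf names with the unit
    separator character, which cannot occur in parsed labels.
    """

    leaves: frozenset
    canonical_key: str

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "CladeSignature":
        leaf_set = frozenset(names)
        return cls(leaf_set, UNIT_SEP.join(sorted(leaf_set)))


def traverse(tree: Tree, order: str = "preorder") -> List[TreeNode]:
    """All nodes of ``tree`` in ``preorder`` or ``postorder``.

    Postorder emits children before their parents; both orders visit
    children in stored (plot) order.
    """
    if order not in ("preorder", "postorder"):
        raise ValueError(f"unknown traversal order {order!r}")
    out: List[TreeNode] = []
    stack: List[tuple] = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if order == "preorder":
            out.append(node)
            stack.extend((c, False) for c in reversed(node.children))
        else:
            if expanded or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))
    return out


def clade_signature(node: TreeNode) -> CladeSignature:
    """Signature of the clade subtended by ``node`` (a leaf is a singleton)."""
    names = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            if n.name is None:
                raise MalformedTreeError("leaf without a Name attribute")
            names.append(n.name)
        else:
            stack.extend(n.children)
    return CladeSignature.from_names(names)


def canonical_key(node: TreeNode) -> str:
    return clade_signature(node).canonical_key


def lca(tree: Tree, names: Iterable[str]) -> TreeNode:
    """Deepest node whose clade contains every name in ``names``."""
    wanted = set(names)
    if not wanted:
        raise NodeLookupError("empty selector")
    present = set(tree.leaf_names())
    missing = wanted - present
    if missing:
        raise NodeLookupError(f"unknown leaf name(s): {sorted(missing)}")
    node = tree.root
    while True:
        for child in node.children:
            if wanted <= clade_signature(child).leaves:
                node = child
                break
        else:
            return node


def node_depths(tree: Tree) -> tuple:
    """Root-to-node path lengths and the tree height.

    Returns ``(depths, height)`` where ``depths`` maps each node to the
    sum of branch lengths from the root (root at 0) and ``height`` is
    the maximum leaf depth. A missing ``Length`` counts as 0.
    """
    depths: Dict[TreeNode, float] = {tree.root: 0.0}
    height = 0.0
    for node in traverse(tree, "preorder"):
        if node is tree.root:
            continue
        length = node.length
        if length is None:
            length = 0.0
        if length < 0:
            raise MalformedTreeError(f"negative branch length {length}")
        depths[node] = depths[node.parent] + length
        if node.is_leaf:
            height = max(height, depths[node])
    return depths, height


def _resolve(tree: Tree, selector: Iterable[str]) -> TreeNode:
    return lca(tree, selector)


def reroot_on_branch(
    tree: Tree, child_selector: Iterable[str], fraction: float = 0.5
) -> Tree:
    """Re-root on the branch above the selected node.

    ``fraction`` places the new root along that branch: 0 at the node
    itself, 1 at its parent. The path from the old attachment point to
    the old root is re-oriented; the total branch length and the leaf
    set are conserved, and a degree-2 old root is suppressed.
    Returns a new tree.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = tree.copy()
    node = _resolve(out, child_selector)
    if node is out.root:
        raise TreeError("selector resolves to the root: no branch to reroot on")
    branch = node.length or 0.0

    parent = node.parent
    parent.remove_child(node)
    new_root = TreeNode()
    new_root.add_child(node)
    node.length = fraction * branch

    # Walk from the old parent up to the old root, reversing each edge:
    # the former parent becomes a child carrying the former child-side
    # length of the edge just reversed.
    attach = new_root
    carry = (1.0 - fraction) * branch
    current: Optional[TreeNode] = parent
    while current is not None:
        upper = current.parent
        if upper is not None:
            upper.remove_child(current)
        own_length = current.length
        if len(current.children) == 1 and upper is None:
            # old root left with a single child: suppress, merging lengths
            only = current.children[0]
            current.remove_child(only)
            only.length = (only.length or 0.0) + carry
            attach.add_child(only)
        else:
            current.length = carry
            attach.add_child(current)
            attach = current
        carry = own_length if own_length is not None else 0.0
        current = upper
    return Tree(new_root)


def prune(tree: Tree, selector: Iterable[str]) -> Tree:
    """Remove the selected clade; suppress any resulting degree-2 node.

    When an internal node is left with a single child, the child absorbs
    the node (lengths added). A root left with a single child is
    replaced by that child (whose own Length is dropped, as a root has
    no subtending branch). Returns a new tree.
    """
    out = tree.copy()
    node = _resolve(out, selector)
    if node is out.root:
        raise TreeError("cannot prune the root (would leave no leaves)")
    parent = node.parent
    parent.remove_child(node)
    while parent is not None and len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        parent.remove_child(only)
        if grand is None:
            only.length = None
            out.root = only
            only.parent = None
        else:
            only.length = (only.length or 0.0) + (parent.length or 0.0)
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand
            parent.parent = None
        parent = grand
    return out


def collapse(tree: Tree, selector: Iterable[str], state: bool = True) -> Tree:
    """Set the collapsed display flag on the selected internal node.

    Collapsing is a flag, not a topology edit, so un-collapsing is
    lossless; layout treats collapsed nodes as terminals. Returns a new
    tree.
    """
    out = tree.copy()
    node = _resolve(out, selector)
    if node.is_leaf:
        raise TreeError("cannot collapse a leaf")
    node.collapsed = bool(state)
    return out


def rotate(tree: Tree, selector: Iterable[str]) -> Tree:
    """Reverse the child order of the selected internal node."""
    out = tree.copy()
    node = _resolve(out, selector)
    if node.is_leaf:
        raise TreeError("cannot rotate a leaf")
    node.children.reverse()
    return out
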