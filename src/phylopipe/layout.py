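"""Tree layouts: map every visible node to plot coordinates.

Three styles are provided:

* ``rectangular`` — tips on an evenly spaced vertical ladder, x
  proportional to depth (branch length from the root);
* ``circular`` — tips on evenly spaced angles, radius proportional to
  depth between an inner and an outer radius;
* ``unrooted`` — the equal-angle algorithm: each subtree receives an
  angular wedge proportional to its number of visible terminals and
  grows along the wedge bisector.

Coordinates follow the screen convention: y increases downward and the
first depth-first terminal sits at the top. Collapsed nodes occupy a
single terminal slot; their subtree is hidden, and the maximum depth of
the hidden clade is kept so the drawing stage can close the collapse
triangle at the right x.

Trees without branch lengths anywhere fall back to unit edge lengths so
that a bare topology such as ``((A,B),C);`` still plots.

Layouts are pure functions of their inputs: identical input gives
bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .tree import Tree, TreeNode, node_depths

__all__ = [
    "LayoutOptions",
    "LayoutResult",
    "visible_terminals",
    "visible_nodes",
    "layout_rectangular",
    "layout_circular",
    "layout_unrooted",
    "compute_layout",
]


@dataclass
class LayoutOptions:
    """Plot geometry parameters (plot units are SVG user units)."""

    style: str = "rectangular"
    width: float = 1000.0
    height: float = 600.0
    inner_radius: float = 0.0
    outer_radius: Optional[float] = None  # default: min(width, height)/2

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.style not in ("rectangular", "circular", "unrooted"):
            raise ValueError(f"unknown layout style {self.style!r}")


@dataclass
class LayoutResult:
    """Per-node plot coordinates produced by a Coordinates stage.

    ``scale`` converts tree depth/age units to plot units;
    ``tip_anchor_x`` is the x of age 0 (rectangular layouts), so every
    age maps to x = tip_anchor_x - age * scale. ``slot`` is the spacing
    between adjacent terminals, and ``collapsed_tip_x`` records, for
    each collapsed node, the x of its hidden clade's deepest leaf.
    """

    style: str
    points: Dict[TreeNode, Tuple[float, float]]
    angles: Dict[TreeNode, float] = field(default_factory=dict)
    scale: float = 1.0
    tip_anchor_x: Optional[float] = None
    slot: float = 0.0
    collapsed_tip_x: Dict[TreeNode, float] = field(default_factory=dict)


def visible_terminals(tree: Tree) -> List[TreeNode]:
    """Leaves and collapsed nodes in depth-first order.

    Traversal never descends into a collapsed node: the node itself is
    the terminal, its subtree is hidden.
    """
    out: List[TreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf or node.collapsed:
            out.append(node)
        else:
            stack.extend(reversed(node.children))
    return out


def visible_nodes(tree: Tree) -> List[TreeNode]:
    """All nodes not hidden inside a collapsed clade (depth-first)."""
    out: List[TreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        out.append(node)
        if not node.collapsed:
            stack.extend(reversed(node.children))
    return out


def _layout_depths(tree: Tree) -> Tuple[Dict[TreeNode, float], float]:
    """Node depths with the unit-edge fallback for length-free trees."""
    depths, height = node_depths(tree)
    if height > 0:
        return depths, height
    depths = {}
    height = 0.0
    stack: List[Tuple[TreeNode, float]] = [(tree.root, 0.0)]
    while stack:
        node, depth = stack.pop()
        depths[node] = depth
        height = max(height, depth)
        stack.extend((c, depth + 1.0) for c in node.children)
    return depths, max(height, 1.0)


def _max_clade_depth(node: TreeNode, depths: Dict[TreeNode, float]) -> float:
    best = depths[node]
    stack = [node]
    while stack:
        n = stack.pop()
        best = max(best, depths[n])
        stack.extend(n.children)
    return best


def layout_rectangular(tree: Tree,
                       options: Optional[LayoutOptions] = None) -> LayoutResult:
    """Rectangular layout: x = depth * scale, tips evenly spaced in y."""
    options = options or LayoutOptions()
    depths, height = _layout_depths(tree)
    scale = options.width / height
    terminals = visible_terminals(tree)
    n = len(terminals)
    slot = options.height / (n - 1) if n > 1 else 0.0
    ys: Dict[TreeNode, float] = {}
    for i, terminal in enumerate(terminals):
        ys[terminal] = i * slot if n > 1 else options.height / 2.0
    result = LayoutResult("rectangular", {}, scale=scale,
                          tip_anchor_x=options.width, slot=slot)
    order = visible_nodes(tree)
    for node in reversed(order):  # children before parents
        if node not in ys:
            ys[node] = sum(ys[c] for c in node.children) / len(node.children)
        result.points[node] = (depths[node] * scale, ys[node])
        if node.collapsed:
            result.collapsed_tip_x[node] = _max_clade_depth(node, depths) * scale
    return result


def layout_circular(tree: Tree,
                    options: Optional[LayoutOptions] = None) -> LayoutResult:
    """Circular layout: evenly spaced terminal angles, radius = depth."""
    options = options or LayoutOptions(style="circular")
    outer = (options.outer_radius if options.outer_radius is not None
             else min(options.width, options.height) / 2.0)
    if outer <= options.inner_radius:
        raise ValueError("outer_radius must exceed inner_radius")
    depths, height = _layout_depths(tree)
    radial_scale = (outer - options.inner_radius) / height
    terminals = visible_terminals(tree)
    n = len(terminals)
    angles: Dict[TreeNode, float] = {}
    for i, terminal in enumerate(terminals):
        angles[terminal] = 2.0 * math.pi * i / n
    cx, cy = options.width / 2.0, options.height / 2.0
    result = LayoutResult("circular", {}, scale=radial_scale)
    order = visible_nodes(tree)
    for node in reversed(order):
        if node not in angles:
            angles[node] = sum(angles[c] for c in node.children) / len(node.children)
        radius = options.inner_radius + depths[node] * radial_scale
        theta = angles[node]
        result.points[node] = (cx + radius * math.cos(theta),
                               cy + radius * math.sin(theta))
        result.angles[node] = theta
        if node.collapsed:
            result.collapsed_tip_x[node] = (
                options.inner_radius
                + _max_clade_depth(node, depths) * radial_scale)
    return result


def layout_unrooted(tree: Tree,
                    options: Optional[LayoutOptions] = None) -> LayoutResult:
    """Equal-angle unrooted layout.

    The root owns the full 2*pi wedge; every child receives a contiguous
    sub-wedge proportional to its count of visible terminals and is
    placed at its parent's position plus Length along the wedge
    bisector. The drawing is finally translated and scaled to fit the
    width x height box preserving aspect ratio.
    """
    options = options or LayoutOptions(style="unrooted")
    counts: Dict[TreeNode, int] = {}

    def count(node: TreeNode) -> int:
        if node.is_leaf or node.collapsed:
            counts[node] = 1
        else:
            counts[node] = sum(count(c) for c in node.children)
        return counts[node]

    total = count(tree.root)
    raw: Dict[TreeNode, Tuple[float, float]] = {tree.root: (0.0, 0.0)}
    angles: Dict[TreeNode, float] = {tree.root: 0.0}

    def place(node: TreeNode, wedge_start: float, wedge_end: float) -> None:
        start = wedge_start
        for child in ([] if node.collapsed else node.children):
            span = (wedge_end - wedge_start) * counts[child] / counts[node]
            bisector = start + span / 2.0
            length = child.length if child.length is not None else 0.0
            px, py = raw[node]
            raw[child] = (px + length * math.cos(bisector),
                          py + length * math.sin(bisector))
            angles[child] = bisector
            place(child, start, start + span)
            start += span

    place(tree.root, 0.0, 2.0 * math.pi)
    del total

    xs = [p[0] for p in raw.values()]
    ys = [p[1] for p in raw.values()]
    span_x = max(xs) - min(xs)
    span_y = max(ys) - min(ys)
    fit = min(options.width / span_x if span_x > 0 else math.inf,
              options.height / span_y if span_y > 0 else math.inf)
    if not math.isfinite(fit):
        fit = 1.0
    offset_x = (options.width - span_x * fit) / 2.0 - min(xs) * fit
    offset_y = (options.height - span_y * fit) / 2.0 - min(ys) * fit
    result = LayoutResult("unrooted", {}, scale=fit)
    for node, (x, y) in raw.items():
        result.points[node] = (x * fit + offset_x, y * fit + offset_y)
        result.angles[node] = angles[node]
    return result


def compute_layout(tree: Tree, options: LayoutOptions) -> LayoutResult:
    """Dispatch on ``options.style``."""
    if options.style == "rectangular":
        return layout_rectangular(tree, options)
    if options.style == "circular":
        return layout_circular(tree, options)
    return layout_unrooted(tree, options)
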