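"""Plot-action stages: graphics primitives and deterministic SVG.

Each plot action converts a tree, a layout and (optionally) extra data
into an ordered list of :class:`Primitive` values — paths and text
runs in plot units. A figure is an ordered list of such layers;
:func:`render_svg` serializes them in painter's order (later layers on
top) as an SVG 1.1 document whose numbers carry exactly 6 significant
digits, so identical input yields byte-identical output.

Axis, violins and HDI bars all place ages through the single affine law
``x = tip_anchor_x - age * scale`` of the rectangular layout.

"Auto colour by node" derives each violin's hue from a 64-bit FNV-1a
hash of the clade's canonical key, so colours are stable across runs
and across re-application of a pipeline to another tree.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
from xml.sax.saxutils import escape

from .ages import AgeDistributionSet, AgeOptions, violin_density
from .formatters import Colour, FormatterSpec, apply_formatter
from .layout import LayoutResult, visible_nodes, visible_terminals
from .tree import Tree, TreeNode, clade_signature

__all__ = [
    "Primitive",
    "BranchStyle",
    "LabelOptions",
    "ScaleAxisOptions",
    "ViolinOptions",
    "TipMarkerOptions",
    "draw_branches",
    "draw_labels",
    "draw_scale_axis",
    "draw_age_violins",
    "draw_tip_markers",
    "render_svg",
    "auto_colour",
]

BLACK = Colour(0, 0, 0)

#: Path commands: ("M", x, y), ("L", x, y),
#: ("A", rx, ry, rotation, large_arc, sweep, x, y), ("C", x1..y3), ("Z",)
PathCommand = Tuple


@dataclass
class Primitive:
    """One drawable element: a path or an anchored text run."""

    kind: str  # "path" | "text"
    path: Tuple[PathCommand, ...] = ()
    text: str = ""
    anchor: Tuple[float, float] = (0.0, 0.0)
    anchor_mode: str = "start"  # start | middle | end
    stroke: Optional[Colour] = None
    stroke_width: float = 1.0
    fill: Optional[Colour] = None
    font_family: str = "Helvetica"
    font_size: float = 10.0

    def __post_init__(self) -> None:
        coords: List[float] = []
        for command in self.path:
            coords.extend(v for v in command[1:] if isinstance(v, float))
        coords.extend(self.anchor)
        if any(not math.isfinite(v) for v in coords):
            raise ValueError("non-finite coordinate in primitive")


@dataclass
class BranchStyle:
    colour: Colour = BLACK
    width: float = 1.0
    shape: str = "elbow"  # elbow | straight | arc


@dataclass
class LabelOptions:
    target: str = "tips"  # tips | internal | branches
    attribute: str = "Name"
    formatter: Optional[FormatterSpec] = None
    font_family: str = "Helvetica"
    font_size: float = 10.0
    dx: float = 0.0
    dy: float = 0.0


@dataclass
class ScaleAxisOptions:
    """Age-axis parameters: tick spacing, range, label digits, units."""

    tick_spacing: float = 100.0
    start: float = 0.0
    end: float = 1000.0
    digits: int = 0
    units: str = ""
    font_family: str = "Helvetica"
    font_size: float = 10.0
    margin: float = 20.0

    def __post_init__(self) -> None:
        if self.tick_spacing <= 0:
            raise ValueError("tick_spacing must be positive")
        if self.end <= self.start:
            raise ValueError("axis end must exceed start")


@dataclass
class ViolinOptions:
    auto_colour: bool = True
    fixed_colour: Colour = Colour(100, 149, 237)
    thickness: float = 10.0
    draw_hdi_bars: bool = False
    density_points: int = 101


@dataclass
class TipMarkerOptions:
    attribute: str = "State"
    shape_map: Dict[str, str] = field(default_factory=dict)
    colour_map: Dict[str, Colour] = field(default_factory=dict)
    size: float = 5.0
    offset: float = 5.0


class DrawError(ValueError):
    pass


# ---------------------------------------------------------------------------
# branches


def draw_branches(tree: Tree, layout: LayoutResult,
                  style: Optional[BranchStyle] = None) -> List[Primitive]:
    """Branch paths for every visible edge, in depth-first order.

    Rectangular elbows draw one horizontal segment per child plus a
    vertical connector from the parent; circular branches are a radial
    segment plus an arc at the parent's radius; ``straight`` joins the
    two node positions directly. A collapsed node additionally emits a
    closed triangle spanning its terminal slot out to the hidden
    clade's deepest x.
    """
    style = style or BranchStyle()
    out: List[Primitive] = []
    for node in visible_nodes(tree):
        if node.parent is not None and node.parent in layout.points:
            out.extend(_edge_paths(node, layout, style))
        if node not in layout.points:
            raise DrawError("layout does not cover a visible node")
        if node.collapsed:
            out.append(_collapse_triangle(node, layout, style))
    return out


def _edge_paths(node: TreeNode, layout: LayoutResult,
                style: BranchStyle) -> List[Primitive]:
    px, py = layout.points[node.parent]
    x, y = layout.points[node]
    stroke = dict(stroke=style.colour, stroke_width=style.width)
    if style.shape == "straight" or layout.style == "unrooted":
        return [Primitive("path", (("M", px, py), ("L", x, y)), **stroke)]
    if layout.style == "circular" and style.shape in ("elbow", "arc"):
        return _circular_edge(node, layout, stroke)
    # rectangular elbow
    return [Primitive("path", (("M", px, y), ("L", x, y)), **stroke),
            Primitive("path", (("M", px, py), ("L", px, y)), **stroke)]


def _circular_edge(node: TreeNode, layout: LayoutResult,
                   stroke: dict) -> List[Primitive]:
    parent = node.parent
    theta_p = layout.angles[parent]
    theta_c = layout.angles[node]
    px, py = layout.points[parent]
    x, y = layout.points[node]
    # centre of the circle the arc lies on
    # parent radius from its point: distance to plot centre is implicit in
    # the layout, so reconstruct via the stored angle
    r_parent = math.hypot(px - _centre(layout)[0], py - _centre(layout)[1])
    cx, cy = _centre(layout)
    ax = cx + r_parent * math.cos(theta_c)
    ay = cy + r_parent * math.sin(theta_c)
    sweep = 1.0 if theta_c > theta_p else 0.0
    large = 1.0 if abs(theta_c - theta_p) > math.pi else 0.0
    arc = Primitive("path", (("M", px, py),
                             ("A", r_parent, r_parent, 0.0, large, sweep,
                              ax, ay)), **stroke)
    radial = Primitive("path", (("M", ax, ay), ("L", x, y)), **stroke)
    return [arc, radial]


def _centre(layout: LayoutResult) -> Tuple[float, float]:
    # circular layouts are centred; recover the centre from stored points
    xs = [p[0] for p in layout.points.values()]
    ys = [p[1] for p in layout.points.values()]
    return ((max(xs) + min(xs)) / 2.0, (max(ys) + min(ys)) / 2.0)


def _collapse_triangle(node: TreeNode, layout: LayoutResult,
                       style: BranchStyle) -> Primitive:
    x, y = layout.points[node]
    tip_x = layout.collapsed_tip_x.get(node, x)
    half = layout.slot / 2.0 if layout.slot else 5.0
    return Primitive("path", (("M", x, y), ("L", tip_x, y - half),
                              ("L", tip_x, y + half), ("Z",)),
                     stroke=style.colour, stroke_width=style.width)


# ---------------------------------------------------------------------------
# labels


def draw_labels(tree: Tree, layout: LayoutResult,
                options: Optional[LabelOptions] = None) -> List[Primitive]:
    """Text labels for tips, internal nodes or branches.

    The attribute value is passed through the formatter (default: text
    unchanged, numbers at 3 significant digits); nodes with no value or
    a formatter returning nothing are skipped.
    """
    options = options or LabelOptions()
    formatter = options.formatter or FormatterSpec()
    out: List[Primitive] = []
    if options.target == "tips":
        nodes = visible_terminals(tree)
    elif options.target == "internal":
        nodes = [n for n in visible_nodes(tree)
                 if not n.is_leaf and not n.collapsed]
    elif options.target == "branches":
        nodes = [n for n in visible_nodes(tree) if n.parent is not None]
    else:
        raise DrawError(f"unknown label target {options.target!r}")
    for node in nodes:
        value = node.attributes.get(options.attribute)
        if value is None:
            continue
        text = apply_formatter(value, formatter)
        if text is None:
            continue
        text = str(text)
        x, y = layout.points[node]
        if options.target == "branches":
            px, _ = layout.points[node.parent]
            anchor = ((px + x) / 2.0 + options.dx, y - 3.0 + options.dy)
            mode = "middle"
        else:
            anchor = (x + 5.0 + options.dx, y + options.dy)
            mode = "start"
        out.append(Primitive("text", text=text, anchor=anchor,
                             anchor_mode=mode, fill=BLACK,
                             font_family=options.font_family,
                             font_size=options.font_size))
    return out


# ---------------------------------------------------------------------------
# scale axis


def age_to_x(age: float, layout: LayoutResult) -> float:
    """The single affine age -> x law of a rectangular layout."""
    if layout.tip_anchor_x is None:
        raise DrawError("layout has no tip anchor (not rectangular)")
    return layout.tip_anchor_x - age * layout.scale


def draw_scale_axis(layout: LayoutResult,
                    options: ScaleAxisOptions) -> List[Primitive]:
    """Horizontal age axis below a rectangular tree plot.

    Ticks run from ``start`` to ``end`` every ``tick_spacing`` age
    units; labels use ``digits`` decimals, with the units string
    appended to the first and last labels only.
    """
    if layout.style != "rectangular":
        raise DrawError("the scale axis supports rectangular layouts only")
    y_axis = max(p[1] for p in layout.points.values()) + options.margin
    ages: List[float] = []
    k = 0
    while True:
        age = options.start + k * options.tick_spacing
        if age > options.end + 1e-9:
            break
        ages.append(age)
        k += 1
    stroke = dict(stroke=BLACK, stroke_width=1.0)
    out = [Primitive("path", (("M", age_to_x(ages[-1], layout), y_axis),
                              ("L", age_to_x(ages[0], layout), y_axis)),
                     **stroke)]
    for index, age in enumerate(ages):
        x = age_to_x(age, layout)
        out.append(Primitive("path", (("M", x, y_axis),
                                      ("L", x, y_axis + 5.0)), **stroke))
        label = f"{age:.{options.digits}f}"
        if options.units and index in (0, len(ages) - 1):
            label = f"{label} {options.units}"
        out.append(Primitive(
            "text", text=label, anchor=(x, y_axis + 8.0 + options.font_size),
            anchor_mode="middle", fill=BLACK,
            font_family=options.font_family, font_size=options.font_size))
    return out


# ---------------------------------------------------------------------------
# age violins


def _fnv1a_64(data: bytes) -> int:
    value = 0xCBF29CE484222325
    for byte in data:
        value ^= byte
        value = (value * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return value


def auto_colour(key: str) -> Colour:
    """Deterministic per-clade colour: FNV-1a hash -> HSV hue."""
    hue = (_fnv1a_64(key.encode("utf-8")) % 360) / 360.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.7, 0.9)
    return Colour(round(r * 255), round(g * 255), round(b * 255))


def draw_age_violins(tree: Tree, layout: LayoutResult,
                     ages: AgeDistributionSet,
                     options: Optional[ViolinOptions] = None) -> List[Primitive]:
    """Violin (mirrored KDE) of the age sample at each summarised node.

    The violin is mirrored about the node's y; ages map to x through
    the layout's affine law. Degenerate samples draw a vertical tick at
    the mean instead. Optional HDI bars span [hdi_low, hdi_high].
    """
    options = options or ViolinOptions()
    if layout.style != "rectangular":
        raise DrawError("age violins support rectangular layouts only")
    if not ages.summaries:
        raise DrawError("no age summaries to draw")
    out: List[Primitive] = []
    for node in visible_nodes(tree):
        if node.is_leaf:
            continue
        key = clade_signature(node).canonical_key
        summary = ages.summaries.get(key)
        if summary is None:
            continue
        colour = auto_colour(key) if options.auto_colour else options.fixed_colour
        _, y = layout.points[node]
        geometry = violin_density(
            ages.samples[key],
            AgeOptions(mass=summary.mass,
                       density_points=options.density_points),
            thickness=options.thickness)
        if geometry.degenerate:
            age, half = geometry.grid[0]
            x = age_to_x(age, layout)
            out.append(Primitive("path", (("M", x, y - half),
                                          ("L", x, y + half)),
                                 stroke=colour, stroke_width=1.5))
        else:
            top = [(age_to_x(age, layout), y - half)
                   for age, half in geometry.grid]
            bottom = [(age_to_x(age, layout), y + half)
                      for age, half in reversed(geometry.grid)]
            commands: List[PathCommand] = [("M",) + top[0]]
            commands.extend(("L",) + p for p in top[1:] + bottom)
            commands.append(("Z",))
            out.append(Primitive("path", tuple(commands), fill=colour,
                                 stroke=None))
        if options.draw_hdi_bars:
            out.append(Primitive(
                "path", (("M", age_to_x(summary.hdi_high, layout), y),
                         ("L", age_to_x(summary.hdi_low, layout), y)),
                stroke=colour, stroke_width=2.0))
    return out


# ---------------------------------------------------------------------------
# tip markers


def _glyph(shape: str, x: float, y: float, size: float) -> Tuple[PathCommand, ...]:
    r = size / 2.0
    if shape == "circle":
        return (("M", x - r, y),
                ("A", r, r, 0.0, 1.0, 1.0, x + r, y),
                ("A", r, r, 0.0, 1.0, 1.0, x - r, y),
                ("Z",))
    if shape == "square":
        return (("M", x - r, y - r), ("L", x + r, y - r),
                ("L", x + r, y + r), ("L", x - r, y + r), ("Z",))
    if shape == "star":
        commands: List[PathCommand] = []
        for i in range(10):
            radius = r if i % 2 == 0 else r * 0.4
            theta = -math.pi / 2.0 + i * math.pi / 5.0
            px = x + radius * math.cos(theta)
            py = y + radius * math.sin(theta)
            commands.append(("M" if i == 0 else "L", px, py))
        commands.append(("Z",))
        return tuple(commands)
    raise DrawError(f"unknown marker shape {shape!r}")


def draw_tip_markers(tree: Tree, layout: LayoutResult,
                     options: TipMarkerOptions) -> Tuple[List[Primitive], List[str]]:
    """One glyph per tip whose categorical attribute value is mapped.

    Returns (primitives, warnings); tips whose value is missing from
    the shape map are skipped with a warning.
    """
    out: List[Primitive] = []
    warnings: List[str] = []
    for tip in visible_terminals(tree):
        value = tip.attributes.get(options.attribute)
        if value is None:
            continue
        value = str(value)
        shape = options.shape_map.get(value)
        if shape is None:
            warnings.append(
                f"tip {tip.name!r}: no marker shape for value {value!r}")
            continue
        colour = options.colour_map.get(value, BLACK)
        x, y = layout.points[tip]
        out.append(Primitive(
            "path", _glyph(shape, x + options.offset + options.size, y,
                           options.size),
            fill=colour, stroke=None))
    return out, warnings


# ---------------------------------------------------------------------------
# SVG rendering


def _fmt(value: float) -> str:
    """Exactly 6 significant digits; negative zero normalised."""
    text = format(float(value), ".6g")
    return "0" if text == "-0" else text


def _text_bbox(primitive: Primitive) -> Tuple[float, float, float, float]:
    # no font engine: width estimated at 0.6 * font size per character
    width = 0.6 * primitive.font_size * len(primitive.text)
    x, y = primitive.anchor
    if primitive.anchor_mode == "middle":
        x -= width / 2.0
    elif primitive.anchor_mode == "end":
        x -= width
    return x, y - primitive.font_size, x + width, y + 0.25 * primitive.font_size


def _path_bbox(primitive: Primitive) -> Optional[Tuple[float, float, float, float]]:
    xs: List[float] = []
    ys: List[float] = []
    for command in primitive.path:
        if command[0] in ("M", "L"):
            xs.append(command[1])
            ys.append(command[2])
        elif command[0] == "A":
            xs.extend([command[6], command[6] - command[1],
                       command[6] + command[1]])
            ys.extend([command[7], command[7] - command[2],
                       command[7] + command[2]])
        elif command[0] == "C":
            xs.extend(command[1::2])
            ys.extend(command[2::2])
    if not xs:
        return None
    return min(xs), min(ys), max(xs), max(ys)


def _path_d(path: Tuple[PathCommand, ...]) -> str:
    parts: List[str] = []
    for command in path:
        letter = command[0]
        if letter == "A":
            rx, ry, rot, large, sweep, x, y = command[1:]
            parts.append(f"A {_fmt(rx)} {_fmt(ry)} {_fmt(rot)} "
                         f"{int(large)} {int(sweep)} {_fmt(x)} {_fmt(y)}")
        elif letter == "Z":
            parts.append("Z")
        else:
            parts.append(letter + " " + " ".join(_fmt(v) for v in command[1:]))
    return " ".join(parts)


def _style_attrs(primitive: Primitive) -> str:
    attrs: List[str] = []
    if primitive.fill is not None:
        attrs.append(f'fill="{primitive.fill.css()}"')
        if primitive.fill.a != 255:
            attrs.append(f'fill-opacity="{_fmt(primitive.fill.opacity)}"')
    else:
        attrs.append('fill="none"')
    if primitive.stroke is not None:
        attrs.append(f'stroke="{primitive.stroke.css()}"')
        attrs.append(f'stroke-width="{_fmt(primitive.stroke_width)}"')
        if primitive.stroke.a != 255:
            attrs.append(f'stroke-opacity="{_fmt(primitive.stroke.opacity)}"')
    return " ".join(attrs)


def render_svg(layers: Sequence[Sequence[Primitive]],
               canvas: Optional[Tuple[float, float, float]] = None,
               margin: float = 10.0) -> str:
    """Serialize layers to an SVG 1.1 document (painter's order).

    With ``canvas=(width, height, margin)`` the viewBox is fixed;
    otherwise it is the union of all primitive bounding boxes plus
    ``margin`` (text extents estimated from font size). Byte-identical
    across runs for identical input.
    """
    boxes: List[Tuple[float, float, float, float]] = []
    for layer in layers:
        for primitive in layer:
            box = (_text_bbox(primitive) if primitive.kind == "text"
                   else _path_bbox(primitive))
            if box is not None:
                boxes.append(box)
    if canvas is not None:
        width, height, margin = canvas
        min_x = min_y = -margin
        max_x, max_y = width + margin, height + margin
    elif boxes:
        min_x = min(b[0] for b in boxes) - margin
        min_y = min(b[1] for b in boxes) - margin
        max_x = max(b[2] for b in boxes) + margin
        max_y = max(b[3] for b in boxes) + margin
    else:
        min_x = min_y = 0.0
        max_x = max_y = 1.0
    view = f"{_fmt(min_x)} {_fmt(min_y)} {_fmt(max_x - min_x)} {_fmt(max_y - min_y)}"
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
             f'width="{_fmt(max_x - min_x)}" height="{_fmt(max_y - min_y)}" '
             f'viewBox="{view}">']
    for layer in layers:
        lines.append("<g>")
        for primitive in layer:
            if primitive.kind == "path":
                lines.append(f'<path d="{_path_d(primitive.path)}" '
                             f'{_style_attrs(primitive)}/>')
            else:
                x, y = primitive.anchor
                fill = primitive.fill or BLACK
                lines.append(
                    f'<text x="{_fmt(x)}" y="{_fmt(y)}" '
                    f'text-anchor="{primitive.anchor_mode}" '
                    f'font-family="{escape(primitive.font_family)}" '
                    f'font-size="{_fmt(primitive.font_size)}" '
                    f'fill="{fill.css()}">{escape(primitive.text)}</text>')
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"
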