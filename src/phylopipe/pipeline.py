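"""Pipeline orchestration: from a tree file to a finished figure.

A figure is described by an ordered document of stage descriptors:

* exactly one **transformer** reduces the collection to a single tree
  (consensus or pick-one);
* zero or more **further transformations** edit that tree (reroot,
  prune, collapse, rotate) or attach data to it (set-up-ages);
* exactly one **coordinates** stage lays the tree out;
* one or more **plot actions** draw layers, painted in list order.

Descriptors hold only JSON-serializable parameters, and node selectors
are leaf-name lists resolved by last common ancestor, so a pipeline
document can be saved, reloaded, and re-applied to a different tree
file; selectors that fail to resolve there skip their stage with a
warning instead of aborting.

Running a pipeline is deterministic: identical input bytes give
identical SVG bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional

from . import tree as treecore
from .ages import AgeDistributionSet, AgeOptions, collect_age_samples
from .consensus import ConsensusOptions, consensus, retained_trees
from .draw import (BranchStyle, LabelOptions, Primitive, ScaleAxisOptions,
                   TipMarkerOptions, ViolinOptions, draw_age_violins,
                   draw_branches, draw_labels, draw_scale_axis,
                   draw_tip_markers, render_svg)
from .formatters import Colour, FormatterSpec, parse_css_colour
from .layout import LayoutOptions, LayoutResult, compute_layout
from .tree import NodeLookupError, Tree, TreeCollection

__all__ = [
    "FORMAT_VERSION",
    "StageDescriptor",
    "Pipeline",
    "PipelineError",
    "RunResult",
    "MODULE_REGISTRY",
    "build_default_pipeline",
    "run_pipeline",
    "apply_to_other_tree",
    "serialize_pipeline",
    "deserialize_pipeline",
]

FORMAT_VERSION = 1


class PipelineError(ValueError):
    pass


@dataclass
class StageDescriptor:
    """One pipeline stage: a registered module id plus parameters."""

    stage_type: str  # transformer | further_transformation | coordinates | plot_action
    module_id: str
    parameters: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage_type": self.stage_type, "module_id": self.module_id,
                "parameters": dict(sorted(self.parameters.items()))}


@dataclass
class Pipeline:
    """An ordered, serializable figure recipe."""

    transformer: StageDescriptor
    coordinates: StageDescriptor
    further: List[StageDescriptor] = field(default_factory=list)
    plot_actions: List[StageDescriptor] = field(default_factory=list)
    format_version: int = FORMAT_VERSION

    def stages(self) -> List[StageDescriptor]:
        """Display order: transformer, furthers, coordinates, plot actions."""
        return ([self.transformer] + list(self.further)
                + [self.coordinates] + list(self.plot_actions))


@dataclass
class RunResult:
    final_tree: Tree
    layout: LayoutResult
    svg: str
    warnings: List[str] = field(default_factory=list)
    layers: List[List[Primitive]] = field(default_factory=list)
    ages: Optional[AgeDistributionSet] = None


class _Context:
    def __init__(self, collection: TreeCollection) -> None:
        self.collection = collection
        self.retained: List[Tree] = list(collection.trees)
        self.tree: Optional[Tree] = None
        self.layout: Optional[LayoutResult] = None
        self.ages: Optional[AgeDistributionSet] = None
        self.layers: List[List[Primitive]] = []
        self.warnings: List[str] = []


# ---------------------------------------------------------------------------
# module registry

@dataclass(frozen=True)
class ModuleInfo:
    stage_type: str
    schema: Dict[str, type]  # parameter name -> expected python type
    runner: Callable[[_Context, Dict[str, Any]], None]


def _colour(value, default: Colour) -> Colour:
    if value is None:
        return default
    if isinstance(value, Colour):
        return value
    return parse_css_colour(str(value))


def _formatter(value) -> Optional[FormatterSpec]:
    if value is None:
        return None
    if isinstance(value, FormatterSpec):
        return value
    return FormatterSpec.from_dict(value)


def _run_consensus(ctx: _Context, p: Dict[str, Any]) -> None:
    options = ConsensusOptions(
        method=p.get("method", "greedy"),
        burn_in_fraction=float(p.get("burn_in", 0.0)),
        sample_fraction=float(p.get("sample_fraction", 1.0)),
        threshold=float(p.get("threshold", 0.5)),
        index=int(p.get("index", 0)),
        seed=int(p.get("seed", 0)),
        length_summary=p.get("length_summary", "mean"))
    ctx.retained = retained_trees(ctx.collection, options)
    ctx.tree = consensus(ctx.collection, options)


def _selector(p: Dict[str, Any]) -> List[str]:
    selector = p.get("selector")
    if not selector:
        raise PipelineError("stage requires a 'selector' leaf-name list")
    return list(selector)


def _run_reroot(ctx: _Context, p: Dict[str, Any]) -> None:
    ctx.tree = treecore.reroot_on_branch(ctx.tree, _selector(p),
                                         float(p.get("fraction", 0.5)))


def _run_prune(ctx: _Context, p: Dict[str, Any]) -> None:
    ctx.tree = treecore.prune(ctx.tree, _selector(p))


def _run_collapse(ctx: _Context, p: Dict[str, Any]) -> None:
    ctx.tree = treecore.collapse(ctx.tree, _selector(p),
                                 bool(p.get("state", True)))


def _run_rotate(ctx: _Context, p: Dict[str, Any]) -> None:
    ctx.tree = treecore.rotate(ctx.tree, _selector(p))


def _run_setup_ages(ctx: _Context, p: Dict[str, Any]) -> None:
    options = AgeOptions(mass=float(p.get("mass", 0.89)),
                         density_points=int(p.get("density_points", 101)))
    ctx.ages = collect_age_samples(ctx.retained, ctx.tree, options)
    for key in ctx.ages.unmatched:
        names = key.split(treecore.UNIT_SEP)
        ctx.warnings.append(
            f"clade {{{', '.join(names[:3])}{'...' if len(names) > 3 else ''}}}"
            f" matched no sample tree; no age summary")


def _layout_options(style: str, p: Dict[str, Any]) -> LayoutOptions:
    return LayoutOptions(
        style=style,
        width=float(p.get("width", 1000.0)),
        height=float(p.get("height", 600.0)),
        inner_radius=float(p.get("inner_radius", 0.0)),
        outer_radius=(float(p["outer_radius"])
                      if "outer_radius" in p else None))


def _run_coordinates(style: str):
    def runner(ctx: _Context, p: Dict[str, Any]) -> None:
        ctx.layout = compute_layout(ctx.tree, _layout_options(style, p))
    return runner


def _run_branches(ctx: _Context, p: Dict[str, Any]) -> None:
    style = BranchStyle(colour=_colour(p.get("colour"), Colour(0, 0, 0)),
                        width=float(p.get("width", 1.0)),
                        shape=p.get("shape", "elbow"))
    ctx.layers.append(draw_branches(ctx.tree, ctx.layout, style))


def _run_labels(ctx: _Context, p: Dict[str, Any]) -> None:
    options = LabelOptions(
        target=p.get("target", "tips"),
        attribute=p.get("attribute", "Name"),
        formatter=_formatter(p.get("formatter")),
        font_family=p.get("font_family", "Helvetica"),
        font_size=float(p.get("font_size", 10.0)),
        dx=float(p.get("dx", 0.0)), dy=float(p.get("dy", 0.0)))
    ctx.layers.append(draw_labels(ctx.tree, ctx.layout, options))


def _run_scale_axis(ctx: _Context, p: Dict[str, Any]) -> None:
    options = ScaleAxisOptions(
        tick_spacing=float(p.get("tick_spacing", 100.0)),
        start=float(p.get("start", 0.0)),
        end=float(p.get("end", 1000.0)),
        digits=int(p.get("digits", 0)),
        units=p.get("units", ""),
        font_size=float(p.get("font_size", 10.0)))
    ctx.layers.append(draw_scale_axis(ctx.layout, options))


def _run_age_violins(ctx: _Context, p: Dict[str, Any]) -> None:
    if ctx.ages is None:
        raise PipelineError(
            "age-distributions plot action requires a set-up-ages stage")
    options = ViolinOptions(
        auto_colour=bool(p.get("auto_colour", True)),
        fixed_colour=_colour(p.get("colour"), Colour(100, 149, 237)),
        thickness=float(p.get("thickness", 10.0)),
        draw_hdi_bars=bool(p.get("hdi_bars", False)),
        density_points=int(p.get("density_points", 101)))
    ctx.layers.append(draw_age_violins(ctx.tree, ctx.layout, ctx.ages,
                                       options))


def _run_tip_markers(ctx: _Context, p: Dict[str, Any]) -> None:
    options = TipMarkerOptions(
        attribute=p.get("attribute", "State"),
        shape_map=dict(p.get("shape_map", {})),
        colour_map={k: parse_css_colour(v)
                    for k, v in dict(p.get("colour_map", {})).items()},
        size=float(p.get("size", 5.0)))
    primitives, warnings = draw_tip_markers(ctx.tree, ctx.layout, options)
    ctx.layers.append(primitives)
    ctx.warnings.extend(warnings)


MODULE_REGISTRY: Dict[str, ModuleInfo] = {
    "consensus": ModuleInfo("transformer", {
        "method": str, "burn_in": float, "sample_fraction": float,
        "threshold": float, "index": int, "seed": int,
        "length_summary": str}, _run_consensus),
    "reroot": ModuleInfo("further_transformation",
                         {"selector": list, "fraction": float}, _run_reroot),
    "prune": ModuleInfo("further_transformation",
                        {"selector": list}, _run_prune),
    "collapse": ModuleInfo("further_transformation",
                           {"selector": list, "state": bool}, _run_collapse),
    "rotate": ModuleInfo("further_transformation",
                         {"selector": list}, _run_rotate),
    "set-up-ages": ModuleInfo("further_transformation",
                              {"mass": float, "density_points": int},
                              _run_setup_ages),
    "rectangular": ModuleInfo("coordinates",
                              {"width": float, "height": float},
                              _run_coordinates("rectangular")),
    "circular": ModuleInfo("coordinates",
                           {"width": float, "height": float,
                            "inner_radius": float, "outer_radius": float},
                           _run_coordinates("circular")),
    "unrooted": ModuleInfo("coordinates",
                           {"width": float, "height": float},
                           _run_coordinates("unrooted")),
    "branches": ModuleInfo("plot_action",
                           {"colour": str, "width": float, "shape": str},
                           _run_branches),
    "labels": ModuleInfo("plot_action",
                         {"target": str, "attribute": str, "formatter": dict,
                          "font_family": str, "font_size": float,
                          "dx": float, "dy": float}, _run_labels),
    "scale-axis": ModuleInfo("plot_action",
                             {"tick_spacing": float, "start": float,
                              "end": float, "digits": int, "units": str,
                              "font_size": float}, _run_scale_axis),
    "age-distributions": ModuleInfo("plot_action",
                                    {"auto_colour": bool, "colour": str,
                                     "thickness": float, "hdi_bars": bool,
                                     "density_points": int},
                                    _run_age_violins),
    "tip-markers": ModuleInfo("plot_action",
                              {"attribute": str, "shape_map": dict,
                               "colour_map": dict, "size": float},
                              _run_tip_markers),
}


def _validate_stage(stage: StageDescriptor) -> None:
    info = MODULE_REGISTRY.get(stage.module_id)
    if info is None:
        raise PipelineError(f"unknown module id {stage.module_id!r}")
    if info.stage_type != stage.stage_type:
        raise PipelineError(
            f"module {stage.module_id!r} is a {info.stage_type} stage, "
            f"not {stage.stage_type}")
    unknown = set(stage.parameters) - set(info.schema)
    if unknown:
        raise PipelineError(
            f"module {stage.module_id!r}: unknown parameter(s) "
            f"{sorted(unknown)}")


# ---------------------------------------------------------------------------
# building and running


def build_default_pipeline(collection: TreeCollection) -> Pipeline:
    """The out-of-the-box figure for a freshly opened file.

    A multi-tree file gets a greedy consensus transformer; a single
    tree is picked as-is. The plot is rectangular, with branches, tip
    name labels, and branch-length labels (in that order).
    """
    method = "greedy" if len(collection) > 1 else "pick_index"
    return Pipeline(
        transformer=StageDescriptor("transformer", "consensus",
                                    {"method": method}),
        coordinates=StageDescriptor("coordinates", "rectangular", {}),
        plot_actions=[
            StageDescriptor("plot_action", "branches", {}),
            StageDescriptor("plot_action", "labels",
                            {"target": "tips", "attribute": "Name"}),
            StageDescriptor("plot_action", "labels",
                            {"target": "branches", "attribute": "Length"}),
        ])


def run_pipeline(collection: TreeCollection, pipeline: Pipeline,
                 skip_unresolved: bool = False) -> RunResult:
    """Execute transformer, furthers, coordinates and plot actions.

    Stage failures abort with the stage's display index and module id;
    with ``skip_unresolved`` (pipeline re-application), stages whose
    node selector does not resolve are skipped with a warning instead.
    """
    ctx = _Context(collection)
    for display_index, stage in enumerate(pipeline.stages(), start=1):
        _validate_stage(stage)
        info = MODULE_REGISTRY[stage.module_id]
        try:
            info.runner(ctx, stage.parameters)
        except NodeLookupError as error:
            if skip_unresolved:
                ctx.warnings.append(
                    f"stage {display_index} ({stage.module_id}) skipped: "
                    f"{error}")
                continue
            raise PipelineError(
                f"stage {display_index} ({stage.module_id}) failed: "
                f"{error}") from error
        except (PipelineError, ValueError, treecore.TreeError) as error:
            raise PipelineError(
                f"stage {display_index} ({stage.module_id}) failed: "
                f"{error}") from error
    svg = render_svg(ctx.layers)
    return RunResult(final_tree=ctx.tree, layout=ctx.layout, svg=svg,
                     warnings=ctx.warnings, layers=ctx.layers, ages=ctx.ages)


def apply_to_other_tree(pipeline: Pipeline,
                        collection: TreeCollection) -> RunResult:
    """Re-apply a saved figure recipe to a different tree file.

    Identical to :func:`run_pipeline` except that unresolvable node
    selectors skip their stage with a warning — re-used styles should
    survive missing taxa.
    """
    return run_pipeline(collection, pipeline, skip_unresolved=True)


# ---------------------------------------------------------------------------
# serialization


def serialize_pipeline(pipeline: Pipeline) -> str:
    """Stable JSON text of the pipeline document (round-trips exactly)."""
    document = {
        "format_version": pipeline.format_version,
        "transformer": pipeline.transformer.to_dict(),
        "further": [s.to_dict() for s in pipeline.further],
        "coordinates": pipeline.coordinates.to_dict(),
        "plot_actions": [s.to_dict() for s in pipeline.plot_actions],
    }
    return json.dumps(document, indent=2, sort_keys=True)


def deserialize_pipeline(text: str) -> Pipeline:
    """Parse and validate a pipeline document."""
    try:
        document = json.loads(text)
    except json.JSONDecodeError as error:
        raise PipelineError(f"invalid pipeline document: {error}") from error
    version = document.get("format_version")
    if version != FORMAT_VERSION:
        raise PipelineError(
            f"unsupported pipeline format_version {version!r} "
            f"(this reader supports {FORMAT_VERSION})")

    def stage(data: dict) -> StageDescriptor:
        descriptor = StageDescriptor(data["stage_type"], data["module_id"],
                                     dict(data.get("parameters", {})))
        _validate_stage(descriptor)
        return descriptor

    return Pipeline(
        transformer=stage(document["transformer"]),
        coordinates=stage(document["coordinates"]),
        further=[stage(s) for s in document.get("further", [])],
        plot_actions=[stage(s) for s in document.get("plot_actions", [])],
        format_version=version)
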