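"""Node-age distributions for divergence-time figures.

Given a posterior sample of clock trees and a target (typically
consensus) tree, this module gathers, per clade of the target, the age
of the matching clade in every sample tree that contains it, and
summarises each sample with its mean and a highest-density interval
(HDI, default mass 0.89). Ages are measured from the youngest tip of
each sample tree (tips at age 0), the usual convention for chronograms
with an axis in units such as Mya before present.

The HDI is the *narrowest* closed interval containing the requested
probability mass of the sample — for skewed posteriors it is shorter
and better centred than an equal-tailed interval. It is computed
exactly as the minimal-width window over the sorted sample; ties go to
the window with the smallest start index, for determinism.

Violin geometries are Gaussian kernel density estimates on an
even grid spanning the sample range, with the Silverman-style
bandwidth ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .tree import (Tree, TreeError, UNIT_SEP, node_depths, traverse)

__all__ = [
    "AgeOptions",
    "AgeDistributionSet",
    "AgeSummary",
    "ViolinGeometry",
    "node_ages",
    "collect_age_samples",
    "hdi",
    "violin_density",
]


@dataclass
class AgeOptions:
    """Age-summary parameters: HDI mass (default 0.89) and grid size."""

    mass: float = 0.89
    density_points: int = 101

    def __post_init__(self) -> None:
        if not 0.0 < self.mass <= 1.0:
            raise ValueError("mass must be in (0, 1]")
        if self.density_points < 3:
            raise ValueError("density_points must be >= 3")


@dataclass(frozen=True)
class AgeSummary:
    mean: float
    hdi_low: float
    hdi_high: float
    mass: float


@dataclass
class AgeDistributionSet:
    """Per-clade age samples with mean/HDI summaries.

    ``unmatched`` lists canonical keys of target clades found in no
    sample tree (these get no summary and should be surfaced as
    warnings by callers).
    """

    samples: Dict[str, List[float]] = field(default_factory=dict)
    summaries: Dict[str, AgeSummary] = field(default_factory=dict)
    unmatched: List[str] = field(default_factory=list)


def node_ages(tree: Tree) -> Dict[str, float]:
    """Age of every clade of ``tree``, keyed by canonical clade key.

    age(node) = height - depth(node), with height the maximum leaf
    depth, so the deepest tip sits at age 0.
    """
    depths, height = node_depths(tree)
    ages: Dict[str, float] = {}
    leaf_sets: Dict[int, frozenset] = {}
    for node in traverse(tree, "postorder"):
        if node.is_leaf:
            if node.name is None:
                raise TreeError("leaf without a Name attribute")
            leaves = frozenset([node.name])
        else:
            merged: set = set()
            for child in node.children:
                merged |= leaf_sets[id(child)]
            leaves = frozenset(merged)
        leaf_sets[id(node)] = leaves
        ages[UNIT_SEP.join(sorted(leaves))] = height - depths[node]
    return ages


def hdi(samples: Sequence[float], mass: float = 0.89) -> Tuple[float, float]:
    """Highest-density interval: the narrowest window holding ``mass``.

    Sorts the sample, slides every window of ``ceil(mass * n)``
    consecutive values, and returns the endpoints of the narrowest one
    (ties: smallest start index).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("hdi of an empty sample")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    m = min(n, math.ceil(mass * n))
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + m - 1])


def collect_age_samples(trees: Sequence[Tree], target: Tree,
                        options: AgeOptions = AgeOptions()) -> AgeDistributionSet:
    """Gather per-clade age samples for the internal nodes of ``target``.

    A clade of the target is matched by canonical key in every sample
    tree containing it; clades matched nowhere are recorded in
    ``unmatched`` instead of receiving a summary.
    """
    if not trees:
        raise TreeError("empty sample: no trees to collect ages from")
    target_keys = [key for key, node in _internal_keys(target)]
    result = AgeDistributionSet()
    sample_ages = [node_ages(tree) for tree in trees]
    for key in target_keys:
        values = [ages[key] for ages in sample_ages if key in ages]
        if not values:
            result.unmatched.append(key)
            continue
        low, high = hdi(values, options.mass)
        result.samples[key] = values
        result.summaries[key] = AgeSummary(
            mean=float(np.mean(values)), hdi_low=low, hdi_high=high,
            mass=options.mass)
    return result


def _internal_keys(tree: Tree):
    from .tree import clade_signature
    out = []
    for node in traverse(tree, "preorder"):
        if not node.is_leaf:
            out.append((clade_signature(node).canonical_key, node))
    return out


@dataclass
class ViolinGeometry:
    """Density profile of an age sample in plot units.

    ``grid`` is a list of (age, half_width) pairs; for a degenerate
    sample (n < 2 or zero variance) the geometry collapses to a single
    tick at the sample value with ``degenerate`` set.
    """

    grid: List[Tuple[float, float]]
    degenerate: bool = False


def violin_density(samples: Sequence[float],
                   options: AgeOptions = AgeOptions(),
                   thickness: float = 1.0) -> ViolinGeometry:
    """Gaussian KDE of ``samples`` scaled to a maximum half-width.

    Bandwidth is ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``; the density is
    evaluated at ``options.density_points`` ages evenly spanning the
    sample range and rescaled so its peak equals ``thickness``.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("violin of an empty sample")
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bandwidth = 0.9 * spread * n ** (-0.2)
    if n < 2 or bandwidth <= 0.0:
        return ViolinGeometry([(float(np.mean(x)), thickness)],
                              degenerate=True)
    grid = np.linspace(float(x.min()), float(x.max()),
                       options.density_points)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        n * bandwidth * math.sqrt(2.0 * math.pi))
    half = density * (thickness / density.max())
    return ViolinGeometry(list(zip(grid.tolist(), half.tolist())))
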