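# Methods

phylopipe builds publication figures for phylogenetic trees — in
particular time-calibrated ("clock") trees from Bayesian divergence-time
analyses — as an explicit, serializable pipeline of small stages. This
note records the models, algorithms, defaults and numerical choices, and
what the synthetic-data generator does and does not emulate.

## The pipeline model

A figure is a recipe with four ordered parts:

1. **Transformer** — reduces the tree collection read from one file to a
   single tree (consensus or pick-one).
2. **Further transformations** — edit that tree (reroot, prune, collapse,
   rotate) or attach derived data to it (node-age distributions).
3. **Coordinates** — assigns every visible node a plot position
   (rectangular, circular, or equal-angle unrooted).
4. **Plot actions** — draw layers (branches, labels, scale axis, age
   violins, tip markers) in *painter's order*: later layers on top.

Stages are independent: removing one plot action never changes the
primitives another emits. Recipes serialize to a versioned JSON document
whose node selectors are *sets of leaf names* resolved by last common
ancestor, so a saved recipe can be re-applied to a different tree file;
a selector that does not resolve there skips its stage with a warning
rather than aborting (styles should survive missing taxa). Node indices
were rejected as selectors because they are meaningless across files.

Everything is deterministic: layouts are pure functions, SVG numbers are
printed with exactly 6 significant digits, subsampling and the synthetic
generator are driven by explicit seeds, and all tie-breaks below are
fixed. Re-running a pipeline on the same input reproduces the SVG
byte for byte.

## Tree model and I/O

Trees are rooted, with ordered children (order is what layouts draw) and
an open attribute map per node; `Name`, `Length` and `Support` are
conventional keys. A missing `Length` counts as 0 in depth computations,
and a tree with no lengths anywhere falls back to unit edges so bare
topologies like `((A,B),C);` still plot. Collapsing is a display *flag*,
not a topology edit, so un-collapsing is lossless.

The Newick dialect is Felsenstein's grammar plus Bayesian-output
conventions: `[&key=value,...]` comments become node attributes (numeric
when parseable), `{...}` range values (e.g. BEAST's
`height_95%_HDI={a,b}`) are kept verbatim as text to avoid silent
misparsing, a bare numeric internal label is `Support` (a textual one is
`Name`; both choices are parser options), and underscores are preserved
verbatim by default with the classic underscore-to-space dialect behind
an option. Every parse error carries its character offset. NEXUS support
covers the TREES block with TRANSLATE; a pipeline document can be
embedded in NEXUS output inside a `[!phylopipe-pipeline ...]` comment
whose balanced brackets keep standard readers (verified against
dendropy) happy while this package recovers it byte-exactly. The "memory
vs disk loader" distinction is reduced to a streaming iterator over
NEXUS tree statements.

## Consensus

The transformer drops the first `floor(burn_in_fraction * N)` trees,
then keeps a uniform, seeded, order-preserving subsample of
`floor(sample_fraction * M)` of the remainder. All trees must share one
leaf set (the error reports the symmetric difference).

*Greedy consensus* counts every rooted clade across the retained trees
and accepts clades in decreasing frequency while each remains pairwise
compatible (nested or disjoint) with everything accepted. Equal
frequencies are broken deterministically: smaller clade first, then
lexicographic canonical key — the tie-break is arbitrary but must be
fixed for byte-identical reruns. *Majority-rule* keeps exactly the
clades in strictly more than `threshold` (default 0.5) of the trees; the
strict comparison is what guarantees mutual compatibility by pigeonhole,
so the greedy clade set always contains the majority set. Consensus
nodes carry `Support = count / M` and `Length` = the arithmetic mean of
the clade's branch length over the trees containing it (median
available as an option); the mean is the summary consistent with
plotting mean node ages.

## Node ages and highest-density intervals

Ages are measured from the youngest tip: `age(node) = height −
depth(node)` with height the maximum root-to-leaf path length, matching
the convention of chronogram axes in Mya before present. For a target
(usually consensus) tree, the age of each clade is collected from every
retained sample tree containing the same clade (matched by canonical
leaf-set key); clades matched nowhere are reported as warnings rather
than summarised.

Each sample is summarised by its mean and its **highest-density
interval** (HDI), the *narrowest* closed interval containing the
requested probability mass — shorter and better centred than an
equal-tailed interval for skewed posteriors. Default mass 0.89. It is
computed exactly: sort the sample, slide every window of
`ceil(mass * n)` consecutive values, return the narrowest (ties: the
smallest start index, fixed for determinism). The mean may legitimately
fall outside the HDI for multimodal samples; only `low ≤ high` is
guaranteed.

Violin geometries are Gaussian kernel density estimates on an even grid
(default 101 points) spanning the sample range, with the Silverman-style
bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)`; when the IQR is zero but
the sd is not, the sd alone is used rather than collapsing the bandwidth
to zero. Samples with fewer than two values or zero variance render as a
tick mark instead of a violin, avoiding a division by zero in the
bandwidth. Profiles are rescaled so the peak equals the configured
thickness (default 10 plot units).

## Layouts

All layouts use screen convention (y grows downward; first depth-first
terminal on top) and are pure functions.

* **Rectangular** (default 1000 × 600 plot units): terminal *i* of *n*
  at `y = i · height/(n−1)`; `x = depth · scale` with
  `scale = width / tree height`; internal y is the mean of the immediate
  children's y (not of subtended tips — the standard choice, which also
  balances multifurcations). `tip_anchor_x` is the x of age 0, giving
  the single affine law `x = tip_anchor_x − age · scale` shared by the
  scale axis, violins and HDI bars.
* **Circular**: terminal *i* at angle `2π·i/n`, radius linear in depth
  between the inner (default 0) and outer (default half the canvas)
  radii; internal angle = mean of children's.
* **Unrooted** (equal-angle): the root owns the full `2π` wedge; each
  child receives a contiguous sub-wedge proportional to its visible
  terminal count and grows along the wedge bisector; the drawing is
  finally fitted to the canvas preserving aspect ratio. No daylight
  adjustment is applied.

A collapsed node occupies one terminal slot; its subtree is hidden and
the hidden clade's maximum depth is kept so the branch layer can draw
the collapse triangle out to the right x.

## Drawing and SVG

Plot actions emit lists of path/text primitives in plot units;
`render_svg` serializes layers in order as SVG 1.1 using only `svg`,
`g`, `path` and `text` elements. There is no font engine: text extents
for canvas auto-sizing are estimated at 0.6 × font size per character,
and alignment correctness relies on SVG text-anchor semantics. The
viewBox is the union of primitive bounding boxes plus a margin (default
10 units); one plot unit is one SVG user unit.

The scale axis draws ticks from `start` (default 0) every
`tick_spacing` age units up to `end`, labelled with `digits` decimals;
the units string is appended to the first and last labels only. "Auto
colour by node" would be random in spirit, but random colours break
reproducibility and pipeline re-use, so each violin's colour is derived
from a 64-bit FNV-1a hash of its clade's canonical key mapped to an HSV
hue (s = 0.7, v = 0.9) — stable across runs and across trees sharing the
clade.

## Formatters

Label and colour stages convert attribute values through declarative
formatter specs rather than user-supplied code: a portable, testable
subset covering the standard conversions (round to significant or
decimal digits, drop values outside thresholds, parse numbers, parse
CSS colours, map numbers onto colour gradients). Rounding is
half-away-from-zero (via exact decimal arithmetic); output is plain
decimal for magnitudes in `[1e-4, 1e7)` and scientific otherwise — the
rounding mode and notation switch are conventions fixed here for
determinism. Colour strings accept the 148 CSS named colours (table
taken from matplotlib), `#RGB`/`#RRGGBB`/`#RRGGBBAA`, and
`rgb()`/`rgba()` with alpha in [0, 1]. Branch-length labels default to
3 significant digits.

## The synthetic posterior generator

`yule_tree` draws an exactly ultrametric chronogram from a pure-birth
process (two lineages at time 0; with *k* lineages, wait
`Exponential(k · birth_rate)` and split a uniform lineage; after the
*n*-th leaf appears the tree is cut at the time the next split would
have occurred, so every tip branch has positive length). True node ages
are stored in the `TrueAge` attribute.

`posterior_sample` emulates a Bayesian posterior file: per replicate,
one optional nearest-neighbour-interchange move (probability
`topology_swap_prob`), then all node ages scaled by a single *mean-one*
lognormal factor (`sigma = age_jitter_sd`), clamped from the leaves up
so an NNI cannot leave a child older than its parent, and branch
lengths rebuilt with tips at age 0. The tree-wide factor models
clock-rate uncertainty — the dominant, strongly correlated component of
real node-dating posteriors — and was chosen over independent per-node
jitter deliberately: per-node jitter either violates the age hierarchy
or, once re-sorted/clamped to restore it, acquires order-statistic
biases, whereas the global factor keeps every node's sampled ages
exactly unbiased (their mean recovers `TrueAge`) with relative spread
`sigma`.

Defaults mirror the shape of the worked example's input file: 42 taxa,
1000 trees, birth rate 1 (time units arbitrary; examples rescale to
Mya), age jitter 0.05 (a ~5% relative age spread, typical of a
well-converged node-dating posterior), swap probability 0.05 (most
posterior mass on one topology).

What passing tests on this generator do **not** show: behaviour under
per-node (weakly correlated) age uncertainty, multimodal age
distributions, MCMC autocorrelation, rogue taxa, or trees over
non-identical taxon sets — real posteriors can have all of these, and
the consensus/age machinery handles only the taxon-set mismatch case by
erroring (or warning, for unmatched clades).

## Numerical conventions and degenerate inputs

* Branch lengths must be finite and non-negative; missing = 0.
* Reroot conserves total branch length to < 1e-9 and suppresses the
  degree-2 old root; prune suppresses degree-2 nodes by summing lengths,
  and a root left with one child is replaced by it (its `Length`
  dropped — a root has no subtending branch).
* Round trips (parse∘write) preserve clade sets, child order and
  lengths to ≤ 1e-9 (lengths printed at 12 significant digits).
* Majority threshold comparisons use an absolute 1e-9 guard on the
  clade count to absorb float error in `threshold · M` without
  admitting exact ties.
* Single-terminal layouts centre the terminal; single-sample age
  distributions are degenerate ticks, not errors.

## Problem sizes used in the test suite

The suite validates consensus on 500 random 10-tree/6-taxon collections
against an exhaustive oracle, the HDI on 1000 random samples (n ≤ 200)
against exhaustive window search plus its nominal 89% coverage on 10^5
gamma draws, I/O round trips on 1000 random trees, and the full
clock-figure workflow at the worked example's native scale (1000 trees ×
42 taxa) including byte-identical re-rendering — sizes chosen to match
the scales the package is meant for while keeping the default run fast.
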