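"""Plot actions and SVG serialization: structure, ordering, determinism."""

import math

import pytest
from lxml import etree

from phylopipe import (AgeOptions, BranchStyle, Colour, LabelOptions,
                       ScaleAxisOptions, TipMarkerOptions, ViolinOptions,
                       auto_colour, collapse, collect_age_samples,
                       draw_age_violins, draw_branches, draw_labels,
                       draw_scale_axis, draw_tip_markers, FormatterSpec,
                       layout_rectangular, layout_circular, LayoutOptions,
                       parse_newick, render_svg)
from phylopipe.draw import DrawError, age_to_x, Primitive


@pytest.fixture
def clock_layout(three_leaf):
    return layout_rectangular(three_leaf, LayoutOptions(width=500,
                                                        height=100))


class TestBranches:
    def test_elbow_counts(self, three_leaf, clock_layout):
        primitives = draw_branches(three_leaf, clock_layout)
        horizontals = [p for p in primitives
                       if p.path[0][2] == p.path[1][2]]
        verticals = [p for p in primitives if p.path[0][1] == p.path[1][1]]
        assert len(horizontals) == 4  # one per edge
        assert len(verticals) <= 4

    def test_straight_style_one_per_edge(self, three_leaf, clock_layout):
        primitives = draw_branches(three_leaf, clock_layout,
                                   BranchStyle(shape="straight"))
        assert len(primitives) == 4

    def test_collapsed_triangle_replaces_subtree(self, three_leaf):
        tree = collapse(three_leaf, {"A", "B"}, True)
        layout = layout_rectangular(tree, LayoutOptions(width=500,
                                                        height=100))
        primitives = draw_branches(tree, layout)
        triangles = [p for p in primitives if p.path[-1][0] == "Z"]
        assert len(triangles) == 1
        # edges drawn: root->collapsed, root->C (2 elbow pairs), no A/B
        assert len(primitives) == 4 + 1

    def test_circular_arcs(self):
        tree = parse_newick("((A:1,B:1):1,C:2);").trees[0]
        layout = layout_circular(tree, LayoutOptions(style="circular",
                                                     width=400, height=400))
        primitives = draw_branches(tree, layout)
        arcs = [p for p in primitives if any(c[0] == "A" for c in p.path)]
        assert len(arcs) == 4


class TestLabels:
    def test_tip_names(self, three_leaf, clock_layout):
        primitives = draw_labels(three_leaf, clock_layout)
        assert sorted(p.text for p in primitives) == ["A", "B", "C"]
        assert all(p.anchor_mode == "start" for p in primitives)

    def test_branch_length_labels_formatted(self, clock_layout):
        tree = parse_newick("(A:1,B:2);").trees[0]
        layout = layout_rectangular(tree)
        primitives = draw_labels(tree, layout, LabelOptions(
            target="branches", attribute="Length",
            formatter=FormatterSpec(digits=2, digit_mode="decimal")))
        assert sorted(p.text for p in primitives) == ["1.00", "2.00"]
        assert all(p.anchor_mode == "middle" for p in primitives)

    def test_threshold_removal(self):
        tree = parse_newick("(A:1,B:2);").trees[0]
        layout = layout_rectangular(tree)
        primitives = draw_labels(tree, layout, LabelOptions(
            target="branches", attribute="Length",
            formatter=FormatterSpec(digits=2, digit_mode="decimal",
                                    max_threshold=1.5)))
        assert [p.text for p in primitives] == ["1.00"]


class TestScaleAxis:
    def test_tick_count_and_unit_labels(self, clock_layout):
        options = ScaleAxisOptions(tick_spacing=150, start=0, end=3000,
                                   digits=0, units="Mya")
        primitives = draw_scale_axis(clock_layout, options)
        texts = [p for p in primitives if p.kind == "text"]
        assert len(texts) == 21  # floor(3000/150) + 1
        assert texts[0].text == "0 Mya"
        assert texts[-1].text == "3000 Mya"
        assert all(" " not in p.text for p in texts[1:-1])

    def test_zero_age_tick_at_tip_anchor(self, clock_layout):
        options = ScaleAxisOptions(tick_spacing=1, start=0, end=2)
        primitives = draw_scale_axis(clock_layout, options)
        ticks = [p for p in primitives if p.kind == "path"][1:]
        assert ticks[0].path[0][1] == pytest.approx(
            clock_layout.tip_anchor_x)

    def test_affine_law_across_ticks(self, clock_layout):
        options = ScaleAxisOptions(tick_spacing=0.5, start=0, end=2,
                                   digits=1)
        ticks = [p for p in draw_scale_axis(clock_layout, options)
                 if p.kind == "path"][1:]
        for k, tick in enumerate(ticks):
            age = 0.5 * k
            assert tick.path[0][1] == pytest.approx(
                age_to_x(age, clock_layout))

    def test_rejects_non_rectangular(self):
        tree = parse_newick("((A:1,B:1):1,C:2);").trees[0]
        layout = layout_circular(tree, LayoutOptions(style="circular",
                                                     width=400, height=400))
        with pytest.raises(DrawError):
            draw_scale_axis(layout, ScaleAxisOptions(tick_spacing=1, end=2))


class TestViolins:
    def make_ages(self, tree, n=50, jitter=0.1, seed=0):
        import numpy as np
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n):
            replica = tree.copy()
            for node in replica.root.children:
                if node.length is not None:
                    node.length = float(node.length *
                                        rng.lognormal(0, jitter))
            samples.append(replica)
        return collect_age_samples(samples, tree)

    def test_zero_variance_tick(self, three_leaf, clock_layout):
        ages = collect_age_samples([three_leaf.copy() for _ in range(3)],
                                   three_leaf)
        primitives = draw_age_violins(three_leaf, clock_layout, ages)
        # both internal nodes are zero-variance: two tick marks
        ticks = [p for p in primitives if len(p.path) == 2]
        assert len(ticks) == 2

    def test_violin_extent_maps_sample_range(self, three_leaf, clock_layout):
        ages = self.make_ages(three_leaf)
        primitives = draw_age_violins(three_leaf, clock_layout, ages,
                                      ViolinOptions(auto_colour=False))
        from phylopipe.tree import UNIT_SEP
        root_key = UNIT_SEP.join(["A", "B", "C"])
        polygon = [p for p in primitives if p.path[-1][0] == "Z"]
        xs = [c[1] for p in polygon for c in p.path if len(c) > 2]
        lo = age_to_x(max(max(ages.samples[k]) for k in ages.samples),
                      clock_layout)
        hi = age_to_x(min(min(ages.samples[k]) for k in ages.samples),
                      clock_layout)
        assert min(xs) == pytest.approx(lo)
        assert max(xs) == pytest.approx(hi)

    def test_auto_colours_deterministic(self):
        assert auto_colour("A\x1fB") == auto_colour("A\x1fB")
        assert auto_colour("A\x1fB") != auto_colour("A\x1fC")

    def test_hdi_bars_obey_affine_law(self, three_leaf, clock_layout):
        ages = self.make_ages(three_leaf)
        primitives = draw_age_violins(
            three_leaf, clock_layout, ages,
            ViolinOptions(draw_hdi_bars=True))
        bars = [p for p in primitives if len(p.path) == 2
                and p.path[0][2] == p.path[1][2]]
        summaries = {age_to_x(s.hdi_high, clock_layout):
                     age_to_x(s.hdi_low, clock_layout)
                     for s in ages.summaries.values()}
        for bar in bars:
            x0 = bar.path[0][1]
            assert x0 in [pytest.approx(k) for k in summaries]


class TestTipMarkers:
    def test_mapped_and_warned(self, clock_layout):
        tree = parse_newick(
            "((A[&State=yes]:1,B[&State=no]:1):1,C[&State=maybe]:2);"
        ).trees[0]
        layout = layout_rectangular(tree, LayoutOptions(width=500,
                                                        height=100))
        primitives, warnings = draw_tip_markers(tree, layout,
            TipMarkerOptions(attribute="State",
                             shape_map={"yes": "circle", "no": "square"}))
        assert len(primitives) == 2
        assert len(warnings) == 1 and "maybe" in warnings[0]
        # glyph y equals tip y
        tip_ys = sorted(layout.points[t][1] for t in tree.leaves()[:2])

        def endpoint_ys(p):
            return [c[-1] for c in p.path if c[0] in ("M", "L", "A")]

        glyph_ys = sorted((min(endpoint_ys(p)) + max(endpoint_ys(p))) / 2
                          for p in primitives)
        assert glyph_ys == pytest.approx(tip_ys)

    def test_circle_is_closed_arc_path(self, clock_layout):
        tree = parse_newick("((A[&State=x]:1,B:1):1,C:2);").trees[0]
        layout = layout_rectangular(tree)
        primitives, _ = draw_tip_markers(tree, layout,
            TipMarkerOptions(attribute="State", shape_map={"x": "circle"}))
        path = primitives[0].path
        assert path[-1][0] == "Z"
        assert sum(1 for c in path if c[0] == "A") == 2


class TestRenderSvg:
    def test_empty_document_valid(self):
        svg = render_svg([])
        root = etree.fromstring(svg.encode())
        assert root.tag.endswith("svg")

    def test_deterministic_bytes(self, three_leaf, clock_layout):
        layers = [draw_branches(three_leaf, clock_layout),
                  draw_labels(three_leaf, clock_layout)]
        assert render_svg(layers) == render_svg(layers)

    def test_layer_order_is_painter_order(self, three_leaf, clock_layout):
        branches = draw_branches(three_leaf, clock_layout)
        labels = draw_labels(three_leaf, clock_layout)
        forward = render_svg([branches, labels])
        backward = render_svg([labels, branches])
        assert forward.index("<path") < forward.index("<text")
        assert backward.index("<text") < backward.index("<path")

    def test_validates_with_lxml_and_uses_allowed_elements(self, three_leaf,
                                                           clock_layout):
        layers = [draw_branches(three_leaf, clock_layout),
                  draw_labels(three_leaf, clock_layout)]
        root = etree.fromstring(render_svg(layers).encode())
        ns = "{http://www.w3.org/2000/svg}"
        tags = {el.tag for el in root.iter()}
        assert tags <= {f"{ns}svg", f"{ns}g", f"{ns}path", f"{ns}text"}

    def test_six_significant_digits(self):
        primitive = Primitive("path",
                              (("M", 1.2345678, 0.0),
                               ("L", 123456.789, 1e-7)),
                              stroke=Colour(0, 0, 0))
        svg = render_svg([[primitive]])
        assert "1.23457" in svg
        assert "123457" in svg
        assert "1e-07" in svg

    def test_text_escaped(self):
        primitive = Primitive("text", text="a<b&c", anchor=(0.0, 0.0))
        assert "a&lt;b&amp;c" in render_svg([[primitive]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            Primitive("path", (("M", math.nan, 0.0),))
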