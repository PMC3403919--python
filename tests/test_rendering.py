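"""Visual attribute resolution and SVG/PNG/annotated exports."""

import math

import pytest
from lxml import etree

from fluxmap.balance_validation import validate_reactions
from fluxmap.errors import LayoutCoverageError, NumericError, ValidationError
from fluxmap.flux_mapping import map_slice
from fluxmap.layout_interaction import (
    LayoutResult,
    layout_dot,
    reconnect_label,
    split_label,
)
from fluxmap.network_model import read_network
from fluxmap.rendering import (
    OVERLAY_COLOR,
    StyledGraph,
    StyleOptions,
    export_annotated,
    export_png,
    export_svg,
    quality_color,
    render_svg,
    style_slice,
    thickness_of,
)


def styled_toy(toy, condition="A", **style_kwargs):
    slc = map_slice(toy.network, toy.experiment, condition, "t0")
    layout = layout_dot(slc.network, engine="builtin")
    return slc, style_slice(slc, layout, StyleOptions(**style_kwargs))


class TestThickness:
    def test_linear_map(self):
        opts = StyleOptions(multiplicator=3.0)
        assert thickness_of(2.0, opts) == 6.0

    def test_zero_clamps_to_minimum(self):
        opts = StyleOptions(min_thickness=0.5)
        assert thickness_of(0.0, opts) == 0.5

    def test_doubling_multiplicator(self):
        a = StyleOptions(multiplicator=1.0)
        b = StyleOptions(multiplicator=2.0)
        for f in (0.7, 1.0, 5.0):
            assert thickness_of(f, b) == 2 * thickness_of(f, a)

    def test_monotone_strict_above_clamp(self):
        opts = StyleOptions()
        fs = [0.0, 0.1, 0.4, 0.5, 0.6, 2.0, 10.0]
        ts = [thickness_of(f, opts) for f in fs]
        assert ts == sorted(ts)
        assert ts[-1] > ts[-2] > ts[-3]

    def test_non_finite_rejected(self):
        with pytest.raises(NumericError):
            thickness_of(float("nan"), StyleOptions())


class TestQualityColor:
    def test_anchors_and_midpoint(self):
        assert quality_color(0.0, 0.0, 1.0) == (0, 0, 0)
        assert quality_color(1.0, 0.0, 1.0) == (255, 0, 0)
        # round-half-up: 127.5 -> 128
        assert quality_color(0.5, 0.0, 1.0) == (128, 0, 0)

    def test_clamped_outside_range(self):
        assert quality_color(-5.0, 0.0, 1.0) == (0, 0, 0)
        assert quality_color(99.0, 0.0, 1.0) == (255, 0, 0)

    def test_monotone_in_q(self):
        reds = [quality_color(q / 10, 0.0, 1.0)[0] for q in range(11)]
        assert reds == sorted(reds)

    def test_degenerate_range_black_with_warning(self):
        with pytest.warns(UserWarning):
            assert quality_color(3.0, 1.0, 1.0) == (0, 0, 0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            quality_color(0.5, 1.0, 0.0)


class TestStyleSlice:
    def test_quality_off_all_black(self, seed_toy):
        _, styled = styled_toy(seed_toy, quality_mode="off")
        assert {e.color for e in styled.edges} == {(0, 0, 0)}

    def test_quality_graduation_monotone(self, seed_toy):
        slc, styled = styled_toy(seed_toy, quality_mode="red_graduation")
        by_edge = {(e.source, e.target): e for e in styled.edges}
        reds = {}
        for (u, v), e in by_edge.items():
            rnode = slc.owning_reaction((u, v))
            reds.setdefault(slc.reaction_quality[rnode], set()).add(
                e.color[0])
        items = sorted(reds.items())
        # each quality maps to one red level, increasing with quality
        assert all(len(v) == 1 for _, v in items)
        levels = [v.pop() for _, v in items]
        assert levels == sorted(levels)
        assert levels[0] == 0 and levels[-1] == 255

    def test_invisible_reaction_nodes_keep_edges(self, seed_toy):
        _, plain = styled_toy(seed_toy, node_style="normal")
        _, invisible = styled_toy(seed_toy, node_style="invisible")
        assert len(plain.edges) == len(invisible.edges)
        rxn_nodes = [n for n in invisible.nodes if n.kind == "reaction"]
        assert all(n.opacity == 0.0 for n in rxn_nodes)

    def test_arrowhead_tracks_thickness(self, seed_toy):
        _, styled = styled_toy(seed_toy, multiplicator=2.0, arrow_ratio=1.5)
        for e in styled.edges:
            assert e.arrow_size == pytest.approx(1.5 * e.thickness)

    def test_dashed_iff_zero_edge(self, fba_toy):
        slc = map_slice(fba_toy.network, fba_toy.experiment, "hypoxic", "t0")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout)
        for e in styled.edges:
            assert e.dashed == ((e.source, e.target) in slc.zero_edges)

    def test_missing_coordinates_rejected(self, seed_toy):
        slc = map_slice(seed_toy.network, seed_toy.experiment, "A", "t0")
        empty = LayoutResult(coordinates={}, bounding_box=(10, 10))
        with pytest.raises(LayoutCoverageError):
            style_slice(slc, empty)

    def test_overlay_edges_green_and_extra(self, hub_experiment,
                                           hub_network):
        net = split_label(hub_network, "ATP_c")
        overlay = reconnect_label(net, "ATP_c")
        slc = map_slice(net, hub_experiment, "C1", "T1")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout, overlays=[overlay])
        greens = [e for e in styled.edges if e.overlay]
        assert len(greens) == 3
        assert {e.color for e in greens} == {OVERLAY_COLOR}
        n_base = slc.network.graph.number_of_edges()
        assert len(styled.edges) == n_base + 3


class TestSVG:
    def test_stroke_width_parse_back(self, seed_toy):
        opts = StyleOptions(multiplicator=1.7, min_thickness=0.5)
        slc = map_slice(seed_toy.network, seed_toy.experiment, "A", "t0")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout, opts)
        root = etree.fromstring(render_svg(styled).encode())
        lines = [el for el in root.iter()
                 if el.tag.endswith("line") and el.get("class") == "edge"]
        assert len(lines) == slc.network.graph.number_of_edges()
        seen = sorted(float(el.get("stroke-width")) for el in lines)
        expected = sorted(
            round(max(0.5, 1.7 * slc.flux_of(e)), 3)
            for e in slc.network.graph.edges)
        assert seen == pytest.approx(expected, abs=5e-4)

    def test_dashed_edges_carry_pattern(self, fba_toy, tmp_path):
        slc = map_slice(fba_toy.network, fba_toy.experiment, "hypoxic", "t0")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout)
        path = tmp_path / "map.svg"
        export_svg(styled, path)
        root = etree.parse(str(path)).getroot()
        dashed = [el for el in root.iter() if el.get("stroke-dasharray")]
        assert len(dashed) == len(slc.zero_edges)
        assert dashed[0].get("stroke-dasharray") == "4.000,3.000"

    def test_byte_identical_re_export(self, seed_toy, tmp_path):
        _, styled = styled_toy(seed_toy)
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        export_svg(styled, p1)
        export_svg(styled, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_drawing_is_valid_canvas(self, tmp_path):
        from fluxmap.network_model import MetabolicNetwork

        styled = StyledGraph(nodes=[], edges=[], width=100, height=80,
                             dash_pattern=(4.0, 3.0),
                             base_network=MetabolicNetwork())
        path = tmp_path / "empty.svg"
        export_svg(styled, path)
        root = etree.parse(str(path)).getroot()
        assert root.tag.endswith("svg")
        children = [el for el in root]
        assert len(children) == 1  # just the canvas rect
        assert children[0].get("class") == "canvas"


class TestPNGAndAnnotated:
    def test_png_dimensions_scale_with_dpi(self, seed_toy, tmp_path):
        from PIL import Image

        _, styled = styled_toy(seed_toy)
        path = tmp_path / "map.png"
        export_png(styled, path, dpi=144)
        with Image.open(path) as img:
            assert img.size == (math.ceil(styled.width * 2),
                                math.ceil(styled.height * 2))

    def test_annotated_roundtrip_preserves_visuals(self, seed_toy,
                                                   tmp_path):
        opts = StyleOptions(multiplicator=2.0)
        slc = map_slice(seed_toy.network, seed_toy.experiment, "B", "t0")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout, opts)
        path = tmp_path / "annotated.gml"
        export_annotated(styled, path)
        back = read_network(path)
        for e in styled.edges:
            data = back.graph.edges[e.source, e.target]
            assert data["thickness"] == pytest.approx(e.thickness)
            assert data["dashed"] == int(e.dashed)
        for n in styled.nodes:
            data = back.graph.nodes[n.node_id]
            assert data["x"] == pytest.approx(n.x)
            assert data["y"] == pytest.approx(n.y)

    def test_overlays_omitted_unless_requested(self, hub_experiment,
                                               hub_network, tmp_path):
        net = split_label(hub_network, "ATP_c")
        overlay = reconnect_label(net, "ATP_c")
        slc = map_slice(net, hub_experiment, "C1", "T1")
        layout = layout_dot(slc.network, engine="builtin")
        styled = style_slice(slc, layout, overlays=[overlay])
        without = tmp_path / "plain.gml"
        withov = tmp_path / "overlay.gml"
        export_annotated(styled, without)
        export_annotated(styled, withov, include_overlays=True)
        n_plain = len(read_network(without).graph)
        n_ov = len(read_network(withov).graph)
        assert n_ov == n_plain + 1

    def test_splitting_leaves_residuals_untouched(self, hub_experiment,
                                                  hub_network):
        base = map_slice(hub_network, hub_experiment, "C1", "T1")
        split = map_slice(split_label(hub_network, "ATP_c"),
                          hub_experiment, "C1", "T1")
        res_a = {e.label: e.residual
                 for e in validate_reactions(base).reaction_entries}
        res_b = {e.label: e.residual
                 for e in validate_reactions(split).reaction_entries}
        assert res_a == res_b
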