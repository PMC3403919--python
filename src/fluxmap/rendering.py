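"""Resolve a mapped slice into concrete visual attributes and emit files.

Edge thickness encodes the per-edge substance flux linearly:
``thickness = max(min_thickness, multiplicator * f)``; zero-flux edges
are drawn dashed at minimum thickness so sparse data keeps the topology
visible.  Measurement quality is encoded as a black→red graduation on
the owning reaction's node and all its edges (red = poor: wide
confidence interval or high flux variability); reactions without a
quality value stay black.

Exports: deterministic standalone SVG (byte-identical for identical
inputs — no timestamps), PNG rasterisation at a chosen dpi, and
GML/GraphML with all resolved visual attributes attached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

from .errors import IOFailure, NumericError, ValidationError
from .flux_mapping import FluxMapSlice
from .layout_interaction import ConnectorOverlay, LayoutResult, apply_overlay
from .network_model import (
    CONNECTOR,
    METABOLITE,
    MetabolicNetwork,
    REACTION,
    write_network,
)

__all__ = [
    "StyleOptions",
    "StyledNode",
    "StyledEdge",
    "StyledGraph",
    "thickness_of",
    "quality_color",
    "style_slice",
    "export_svg",
    "export_png",
    "export_annotated",
    "OVERLAY_COLOR",
]

RGB = tuple[int, int, int]

BLACK: RGB = (0, 0, 0)
OVERLAY_COLOR: RGB = (0, 160, 0)

NODE_STYLES = ("normal", "rounded", "small", "invisible")
QUALITY_MODES = ("off", "red_graduation")


@dataclass(frozen=True)
class StyleOptions:
    """Global visual parameters (lengths in points).

    ``multiplicator`` scales every edge thickness; ``arrow_ratio`` sets
    the arrowhead width as a multiple of the line thickness;
    ``node_style`` applies to reaction nodes only; ``quality_range``
    ``None`` means auto (min/max of the qualities present in the slice);
    ``invert_quality`` flips the graduation for datasets where a larger
    quality value means *better*.
    """

    multiplicator: float = 1.0
    min_thickness: float = 0.5
    arrow_ratio: float = 1.5
    node_style: str = "normal"
    labels_on: bool = True
    quality_mode: str = "off"
    quality_range: tuple[float, float] | None = None
    invert_quality: bool = False
    zero_dash_pattern: tuple[float, float] = (4.0, 3.0)

    def __post_init__(self) -> None:
        for name in ("multiplicator", "min_thickness", "arrow_ratio"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)
                    and v > 0):
                raise ValidationError(f"{name} must be positive, got {v!r}")
        if self.node_style not in NODE_STYLES:
            raise ValidationError(f"node_style must be one of {NODE_STYLES}")
        if self.quality_mode not in QUALITY_MODES:
            raise ValidationError(
                f"quality_mode must be one of {QUALITY_MODES}")
        if self.quality_range is not None:
            lo, hi = self.quality_range
            if not lo < hi:
                raise ValidationError(
                    f"quality_range must have q_low < q_high, got "
                    f"{self.quality_range!r}")
        if not all(d > 0 for d in self.zero_dash_pattern):
            raise ValidationError("dash pattern lengths must be positive")


@dataclass(frozen=True)
class StyledNode:
    node_id: str
    x: float
    y: float
    shape: str                     # ellipse | rect | rounded_rect
    width: float
    height: float
    fill: RGB
    label: str | None
    opacity: float = 1.0
    kind: str = METABOLITE


@dataclass(frozen=True)
class StyledEdge:
    source: str
    target: str
    x1: float
    y1: float
    x2: float
    y2: float
    thickness: float
    color: RGB
    dashed: bool
    arrow_size: float
    overlay: bool = False


@dataclass
class StyledGraph:
    """Fully resolved drawing, ready for SVG/PNG/GraphML emission."""

    nodes: list[StyledNode]
    edges: list[StyledEdge]
    width: float
    height: float
    dash_pattern: tuple[float, float]
    base_network: MetabolicNetwork
    overlays: tuple[ConnectorOverlay, ...] = ()


def thickness_of(f: float, opts: StyleOptions) -> float:
    """Linear thickness map with a lower clamp: max(min, mult * f)."""
    if not math.isfinite(f):
        raise NumericError(f"non-finite flux {f!r}")
    return max(opts.min_thickness, opts.multiplicator * f)


def quality_color(q: float, q_low: float, q_high: float) -> RGB:
    """Black→red graduation: (0,0,0) at ``q_low``, (255,0,0) at ``q_high``.

    A degenerate range (q_low == q_high) yields black everywhere, with a
    warning.  Channel rounding is half-up so the midpoint maps to 128.
    """
    if q_low == q_high:
        warnings.warn("degenerate quality range; all colors black",
                      stacklevel=2)
        return BLACK
    if q_low > q_high:
        raise ValidationError(f"q_low {q_low} > q_high {q_high}")
    t = (q - q_low) / (q_high - q_low)
    t = min(1.0, max(0.0, t))
    return (int(math.floor(255 * t + 0.5)), 0, 0)


# ---------------------------------------------------------------------------
# Style resolution
# ---------------------------------------------------------------------------

_MET_SIZE = (64.0, 28.0)
_RXN_SIZES = {"normal": (42.0, 20.0), "rounded": (42.0, 20.0),
              "small": (10.0, 10.0), "invisible": (6.0, 6.0)}


def _parse_fill(value) -> RGB | None:
    if isinstance(value, (tuple, list)) and len(value) == 3:
        return tuple(int(c) for c in value)  # type: ignore[return-value]
    if isinstance(value, str) and value.startswith("#") and len(value) == 7:
        return tuple(int(value[i:i + 2], 16) for i in (1, 3, 5))  # type: ignore
    return None


def _auto_range(slc: FluxMapSlice) -> tuple[float, float]:
    qs = sorted(slc.reaction_quality.values())
    if not qs:
        return (0.0, 0.0)
    return (qs[0], qs[-1])


def style_slice(slc: FluxMapSlice, layout: LayoutResult,
                opts: StyleOptions = StyleOptions(),
                overlays: tuple[ConnectorOverlay, ...] | list = ()
                ) -> StyledGraph:
    """Resolve a slice + layout + options into a :class:`StyledGraph`.

    Edges inherit the quality color of their owning reaction; the
    reaction node fill carries it as well, so even "invisible" reaction
    nodes convey quality through their edges.  Overlay connectors are
    placed at the centroid of their member clones and drawn green.
    """
    layout.require_coverage(slc.network)
    net = slc.network
    coords = layout.coordinates

    if opts.quality_mode == "red_graduation":
        q_range = opts.quality_range or _auto_range(slc)
        if opts.invert_quality:
            lo, hi = q_range
            def q_of(q: float) -> float:
                return lo + hi - q
        else:
            def q_of(q: float) -> float:
                return q
        with warnings.catch_warnings():
            if q_range[0] == q_range[1]:
                warnings.simplefilter("ignore")
            rxn_color = {
                r: quality_color(q_of(q), *q_range)
                for r, q in slc.reaction_quality.items()}
    else:
        rxn_color = {}

    nodes: list[StyledNode] = []
    for n in sorted(net.graph.nodes):
        data = net.graph.nodes[n]
        x, y = coords[n]
        if data["kind"] == METABOLITE:
            fill = _parse_fill(data.get("fill")) or (255, 255, 255)
            nodes.append(StyledNode(
                node_id=n, x=x, y=y, shape="ellipse",
                width=_MET_SIZE[0], height=_MET_SIZE[1], fill=fill,
                label=data["label"], kind=METABOLITE))
        else:
            style = opts.node_style
            w, h = _RXN_SIZES[style]
            shape = "rounded_rect" if style == "rounded" else "rect"
            nodes.append(StyledNode(
                node_id=n, x=x, y=y, shape=shape, width=w, height=h,
                fill=rxn_color.get(n, BLACK) if rxn_color else (230, 230, 230),
                label=data["label"] if (opts.labels_on
                                        and style in ("normal", "rounded"))
                else None,
                opacity=0.0 if style == "invisible" else 1.0,
                kind=REACTION))

    edges: list[StyledEdge] = []
    for u, v in sorted(net.graph.edges):
        f = slc.flux_of((u, v))
        dashed = (u, v) in slc.zero_edges
        th = thickness_of(f, opts)
        rnode = slc.owning_reaction((u, v))
        color = rxn_color.get(rnode, BLACK)
        (x1, y1), (x2, y2) = coords[u], coords[v]
        edges.append(StyledEdge(
            source=u, target=v, x1=x1, y1=y1, x2=x2, y2=y2,
            thickness=th, color=color, dashed=dashed,
            arrow_size=opts.arrow_ratio * th))

    for ov in overlays:
        members = sorted(ov.member_ids)
        cx = sum(coords[m][0] for m in members) / len(members)
        cy = sum(coords[m][1] for m in members) / len(members)
        nodes.append(StyledNode(
            node_id=ov.connector_node_id, x=cx, y=cy, shape="ellipse",
            width=18.0, height=18.0, fill=OVERLAY_COLOR, label=ov.label,
            kind=CONNECTOR))
        for _, member in ov.overlay_edges:
            mx, my = coords[member]
            edges.append(StyledEdge(
                source=ov.connector_node_id, target=member,
                x1=cx, y1=cy, x2=mx, y2=my,
                thickness=opts.min_thickness, color=OVERLAY_COLOR,
                dashed=False, arrow_size=0.0, overlay=True))

    return StyledGraph(nodes=nodes, edges=edges,
                       width=layout.bounding_box[0],
                       height=layout.bounding_box[1],
                       dash_pattern=opts.zero_dash_pattern,
                       base_network=net, overlays=tuple(overlays))


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _rgb(color: RGB) -> str:
    return f"rgb({color[0]},{color[1]},{color[2]})"


def _arrow_polygon(e: StyledEdge) -> str | None:
    dx, dy = e.x2 - e.x1, e.y2 - e.y1
    length = math.hypot(dx, dy)
    if length == 0 or e.arrow_size <= 0:
        return None
    ux, uy = dx / length, dy / length
    size = e.arrow_size
    tipx, tipy = e.x2, e.y2
    bx, by = tipx - ux * size * 1.6, tipy - uy * size * 1.6
    px, py = -uy, ux
    p1 = (bx + px * size / 2, by + py * size / 2)
    p2 = (bx - px * size / 2, by - py * size / 2)
    pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in
                   ((tipx, tipy), p1, p2))
    return (f'<polygon class="arrow" points="{pts}" '
            f'fill="{_rgb(e.color)}" />')


def render_svg(styled: StyledGraph) -> str:
    """The SVG document as a string (deterministic, no timestamps)."""
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{_fmt(styled.width)}" height="{_fmt(styled.height)}" '
        f'viewBox="0 0 {_fmt(styled.width)} {_fmt(styled.height)}">',
        '<rect class="canvas" x="0" y="0" '
        f'width="{_fmt(styled.width)}" height="{_fmt(styled.height)}" '
        'fill="white" />',
    ]
    dash = ",".join(_fmt(d) for d in styled.dash_pattern)
    for e in styled.edges:
        cls = "overlay" if e.overlay else "edge"
        parts = [
            f'<line class="{cls}" x1="{_fmt(e.x1)}" y1="{_fmt(e.y1)}"',
            f'x2="{_fmt(e.x2)}" y2="{_fmt(e.y2)}"',
            f'stroke="{_rgb(e.color)}"',
            f'stroke-width="{_fmt(e.thickness)}"',
        ]
        if e.dashed:
            parts.append(f'stroke-dasharray="{dash}"')
        out.append(" ".join(parts) + " />")
        if not e.overlay:
            arrow = _arrow_polygon(e)
            if arrow:
                out.append(arrow)
    for n in styled.nodes:
        opacity = "" if n.opacity == 1.0 else f' opacity="{_fmt(n.opacity)}"'
        if n.shape == "ellipse":
            out.append(
                f'<ellipse class="node" cx="{_fmt(n.x)}" cy="{_fmt(n.y)}" '
                f'rx="{_fmt(n.width / 2)}" ry="{_fmt(n.height / 2)}" '
                f'fill="{_rgb(n.fill)}" stroke="black" '
                f'stroke-width="1.000"{opacity} />')
        else:
            rx = ' rx="6.000"' if n.shape == "rounded_rect" else ""
            out.append(
                f'<rect class="node" x="{_fmt(n.x - n.width / 2)}" '
                f'y="{_fmt(n.y - n.height / 2)}" '
                f'width="{_fmt(n.width)}" height="{_fmt(n.height)}"{rx} '
                f'fill="{_rgb(n.fill)}" stroke="black" '
                f'stroke-width="1.000"{opacity} />')
        if n.label is not None and n.opacity > 0:
            out.append(
                f'<text class="label" x="{_fmt(n.x)}" '
                f'y="{_fmt(n.y + 3)}" text-anchor="middle" '
                f'font-size="9">{escape(n.label)}</text>')
    out.append("</svg>")
    return "\n".join(out) + "\n"


def export_svg(styled: StyledGraph, path) -> None:
    """Write the SVG file; identical inputs yield byte-identical output."""
    try:
        Path(path).write_text(render_svg(styled), encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot write {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# PNG (rasterised with Pillow at dpi/72 scale)
# ---------------------------------------------------------------------------

def export_png(styled: StyledGraph, path, dpi: float = 72.0) -> None:
    """Rasterise the drawing; image size = SVG size * dpi / 72."""
    from PIL import Image, ImageDraw

    scale = dpi / 72.0
    size = (max(1, math.ceil(styled.width * scale)),
            max(1, math.ceil(styled.height * scale)))
    img = Image.new("RGB", size, "white")
    draw = ImageDraw.Draw(img)
    for e in styled.edges:
        w = max(1, round(e.thickness * scale))
        p1 = (e.x1 * scale, e.y1 * scale)
        p2 = (e.x2 * scale, e.y2 * scale)
        if e.dashed:
            _dashed_line(draw, p1, p2,
                         tuple(d * scale for d in styled.dash_pattern),
                         e.color, w)
        else:
            draw.line([p1, p2], fill=e.color, width=w)
    for n in styled.nodes:
        if n.opacity == 0:
            continue
        box = [(n.x - n.width / 2) * scale, (n.y - n.height / 2) * scale,
               (n.x + n.width / 2) * scale, (n.y + n.height / 2) * scale]
        if n.shape == "ellipse":
            draw.ellipse(box, fill=n.fill, outline=(0, 0, 0))
        else:
            draw.rectangle(box, fill=n.fill, outline=(0, 0, 0))
        if n.label is not None:
            draw.text((n.x * scale, n.y * scale), n.label,
                      fill=(0, 0, 0), anchor="mm")
    try:
        img.save(path, format="PNG")
    except OSError as exc:
        raise IOFailure(f"cannot write {path!r}: {exc}") from exc


def _dashed_line(draw, p1, p2, pattern, color, width) -> None:
    x1, y1 = p1
    x2, y2 = p2
    total = math.hypot(x2 - x1, y2 - y1)
    if total == 0:
        return
    ux, uy = (x2 - x1) / total, (y2 - y1) / total
    on, off = pattern
    pos = 0.0
    while pos < total:
        end = min(pos + on, total)
        draw.line([(x1 + ux * pos, y1 + uy * pos),
                   (x1 + ux * end, y1 + uy * end)], fill=color, width=width)
        pos = end + off


# ---------------------------------------------------------------------------
# Annotated GML/GraphML
# ---------------------------------------------------------------------------

def export_annotated(styled: StyledGraph, path, format: str | None = None,
                     include_overlays: bool = False) -> None:
    """Write the network with resolved visual attributes attached.

    Node attributes: ``x``, ``y``, ``fill``; edge attributes:
    ``thickness``, ``dashed`` (0/1), ``fill``.  Overlays are omitted
    unless ``include_overlays`` is set.
    """
    net = styled.base_network.copy()
    if include_overlays:
        for ov in styled.overlays:
            net = apply_overlay(net, ov)
    node_style = {n.node_id: n for n in styled.nodes}
    edge_style = {(e.source, e.target): e for e in styled.edges}
    g = net.graph
    for n in list(g.nodes):
        st = node_style.get(n)
        if st is None:
            continue
        g.nodes[n].update(x=float(st.x), y=float(st.y),
                          fill="#%02x%02x%02x" % st.fill)
    for uv in list(g.edges):
        st = edge_style.get(uv)
        if st is None:
            continue
        g.edges[uv].update(thickness=float(st.thickness),
                           dashed=int(st.dashed),
                           fill="#%02x%02x%02x" % st.color)
    write_network(net, path, format)
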