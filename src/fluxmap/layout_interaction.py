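"""Layout and interaction operators as pure graph transformations.

Hub metabolites (ATP, CO2, ...) touch many reactions and tangle any
layout.  *Splitting* replaces such a node by one clone per incident
reaction; *reconnecting* temporarily overlays a connector node plus one
edge per clone so the eye can still track the shared substance.  Both are
pure: they return new objects and never mutate their input.

Coordinates come either from the external graphviz ``dot`` engine
(hierarchical layout; used when found on PATH) or from a built-in,
fully deterministic layered layout (longest-path layering, barycenter
ordering within layers).  The coordinate convention is screen-style:
origin top-left, y growing downward, units in points.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import (
    AlreadySplit,
    LayoutCoverageError,
    NoSuchLabel,
    NotSplit,
    NothingToConnect,
)
from .network_model import CONNECTOR, MetabolicNetwork, metabolite_id

__all__ = [
    "LayoutResult",
    "ConnectorOverlay",
    "rank_by_degree",
    "split_label",
    "unsplit_label",
    "reconnect_label",
    "apply_overlay",
    "remove_overlay",
    "emit_dot",
    "layout_dot",
]

LAYER_SEP = 90.0   # points between ranks
NODE_SEP = 80.0    # points between nodes within a rank
MARGIN = 40.0


@dataclass(frozen=True)
class LayoutResult:
    """Node coordinates plus the enclosing canvas size (points)."""

    coordinates: dict[str, tuple[float, float]]
    bounding_box: tuple[float, float]
    engine: str = "builtin"
    fallback: bool = False

    def require_coverage(self, network: MetabolicNetwork) -> None:
        missing = [n for n in network.graph.nodes
                   if n not in self.coordinates]
        if missing:
            raise LayoutCoverageError(
                f"layout misses {len(missing)} node(s), e.g. {missing[0]!r}")


@dataclass(frozen=True)
class ConnectorOverlay:
    """Temporary connector re-linking all clones of one label.

    Purely visual: carries no flux, is excluded from balance validation
    and omitted from standard exports unless explicitly requested.
    """

    label: str
    connector_node_id: str
    member_ids: frozenset[str]
    overlay_edges: tuple[tuple[str, str], ...]


# ---------------------------------------------------------------------------
# Degree ranking and splitting
# ---------------------------------------------------------------------------

def rank_by_degree(network: MetabolicNetwork
                   ) -> list[tuple[str, int]]:
    """Metabolite labels by total degree (summed over clones), descending.

    Ties are broken lexicographically — the shell user's "node list
    sorted by degree of interconnection".
    """
    g = network.graph
    totals: dict[str, int] = {}
    for n in network.metabolite_nodes():
        label = network.label(n)
        totals[label] = totals.get(label, 0) + g.in_degree(n) + \
            g.out_degree(n)
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def split_label(network: MetabolicNetwork, label: str) -> MetabolicNetwork:
    """Split a hub metabolite into one clone per incident reaction.

    Clone indices 1..k are assigned in ascending order of reaction label;
    a reaction in which the metabolite appears on both sides gets a single
    clone carrying both edges.  A metabolite touching <= 1 reaction is
    returned unchanged.
    """
    clones = network.nodes_for_label(label)
    if not clones:
        raise NoSuchLabel(f"no metabolite labeled {label!r}")
    if len(clones) > 1 or network.clone(clones[0]) != 0:
        raise AlreadySplit(f"{label!r} is already split")
    node = clones[0]
    g = network.graph
    reactions = sorted({*g.predecessors(node), *g.successors(node)},
                       key=network.label)
    if len(reactions) <= 1:
        return network.copy()

    result = network.copy()
    base_attrs = {k: v for k, v in g.nodes[node].items()
                  if k not in ("kind", "label", "clone")}
    in_edges = list(g.in_edges(node, data=True))
    out_edges = list(g.out_edges(node, data=True))
    result.graph.remove_node(node)
    for i, rnode in enumerate(reactions, start=1):
        clone = result.add_metabolite(label, clone=i, **base_attrs)
        for u, _, data in in_edges:
            if u == rnode:
                result.graph.add_edge(u, clone, **data)
        for _, v, data in out_edges:
            if v == rnode:
                result.graph.add_edge(clone, v, **data)
    result.validate()
    return result


def unsplit_label(network: MetabolicNetwork, label: str) -> MetabolicNetwork:
    """Merge all clones of a label back into a single clone-0 node."""
    clones = network.nodes_for_label(label)
    if not clones:
        raise NoSuchLabel(f"no metabolite labeled {label!r}")
    if len(clones) == 1 and network.clone(clones[0]) == 0:
        raise NotSplit(f"{label!r} is not split")
    result = network.copy()
    g = result.graph
    # clone attributes are copies of the clone-0 originals; take the first
    base_attrs = {k: v for k, v in g.nodes[clones[0]].items()
                  if k not in ("kind", "label", "clone")}
    in_edges = []
    out_edges = []
    for c in clones:
        in_edges += list(g.in_edges(c, data=True))
        out_edges += list(g.out_edges(c, data=True))
        g.remove_node(c)
    merged = result.add_metabolite(label, clone=0, **base_attrs)
    for u, _, data in in_edges:
        g.add_edge(u, merged, **data)
    for _, v, data in out_edges:
        g.add_edge(merged, v, **data)
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Connector overlays
# ---------------------------------------------------------------------------

def _connector_id(label: str) -> str:
    return f"C::{label}"


def reconnect_label(target, label: str) -> ConnectorOverlay:
    """Build the temporary connector overlay for a split label.

    ``target`` may be a network or a mapped slice.  The base graph is not
    touched; overlays for different labels coexist.
    """
    network: MetabolicNetwork = getattr(target, "network", target)
    clones = network.nodes_for_label(label)
    if len(clones) < 2:
        raise NothingToConnect(
            f"{label!r} has {len(clones)} clone(s); need at least 2")
    connector = _connector_id(label)
    return ConnectorOverlay(
        label=label,
        connector_node_id=connector,
        member_ids=frozenset(clones),
        overlay_edges=tuple((connector, c) for c in sorted(clones)),
    )


def apply_overlay(network: MetabolicNetwork,
                  overlay: ConnectorOverlay) -> MetabolicNetwork:
    """Materialize an overlay into a copy of the network (for export)."""
    result = network.copy()
    result.graph.add_node(overlay.connector_node_id, kind=CONNECTOR,
                          label=overlay.label, overlay=1)
    for u, v in overlay.overlay_edges:
        result.graph.add_edge(u, v, overlay=1)
    result.validate()
    return result


def remove_overlay(network: MetabolicNetwork,
                   overlay: ConnectorOverlay) -> MetabolicNetwork:
    """Strip a materialized overlay; exact inverse of :func:`apply_overlay`."""
    result = network.copy()
    if overlay.connector_node_id in result.graph:
        result.graph.remove_node(overlay.connector_node_id)
    return result


# ---------------------------------------------------------------------------
# DOT emission and layout
# ---------------------------------------------------------------------------

def emit_dot(network: MetabolicNetwork, orientation: str = "TB") -> str:
    """Deterministic DOT text for the external hierarchical engine."""
    if orientation not in ("TB", "LR"):
        raise ValueError(f"orientation must be 'TB' or 'LR', got {orientation!r}")
    ids = {n: f"n{i}" for i, n in enumerate(sorted(network.graph.nodes))}
    lines = ["digraph fluxmap {", f"  rankdir={orientation};"]
    for n in sorted(network.graph.nodes):
        label = network.label(n).replace('"', r'\"')
        lines.append(f'  {ids[n]} [label="{label}"];')
    for u, v in sorted(network.graph.edges):
        lines.append(f"  {ids[u]} -> {ids[v]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_available() -> bool:
    return shutil.which("dot") is not None


def _layout_with_dot(network: MetabolicNetwork,
                     orientation: str) -> LayoutResult:
    ids = {f"n{i}": n for i, n in enumerate(sorted(network.graph.nodes))}
    text = emit_dot(network, orientation)
    out = subprocess.run(["dot", "-Tplain"], input=text.encode(),
                         capture_output=True, check=True).stdout.decode()
    coords: dict[str, tuple[float, float]] = {}
    height = 0.0
    width = 0.0
    for line in out.splitlines():
        parts = line.split()
        if parts and parts[0] == "graph":
            width, height = float(parts[2]) * 72, float(parts[3]) * 72
        elif parts and parts[0] == "node":
            name, x, y = parts[1], float(parts[2]), float(parts[3])
            # dot's y grows upward; flip to screen convention
            coords[ids[name]] = (x * 72, height - y * 72)
    result = LayoutResult(coordinates=coords,
                          bounding_box=(width, height), engine="dot")
    result.require_coverage(network)
    return result


def _layering(g: nx.DiGraph) -> dict[str, int]:
    """Longest-path layering; cycles are broken along a deterministic DFS."""
    order = sorted(g.nodes)
    acyclic = nx.DiGraph()
    acyclic.add_nodes_from(order)
    state: dict[str, int] = {}  # 0 = on stack, 1 = done

    def visit(start: str) -> None:
        stack = [(start, iter(sorted(g.successors(start))))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for succ in it:
                if succ not in state:
                    acyclic.add_edge(node, succ)
                    state[succ] = 0
                    stack.append((succ, iter(sorted(g.successors(succ)))))
                    advanced = True
                    break
                if state[succ] == 1:  # forward/cross edge: keep
                    acyclic.add_edge(node, succ)
                # state 0 = back edge: drop to break the cycle
            if not advanced:
                state[node] = 1
                stack.pop()

    for n in order:
        if n not in state:
            visit(n)

    layers = {n: 0 for n in order}
    for n in nx.topological_sort(acyclic):
        for succ in acyclic.successors(n):
            layers[succ] = max(layers[succ], layers[n] + 1)
    return layers


def _builtin_layout(network: MetabolicNetwork,
                    orientation: str) -> LayoutResult:
    g = network.graph
    if len(g) == 0:
        return LayoutResult(coordinates={}, bounding_box=(2 * MARGIN,
                                                          2 * MARGIN),
                            engine="builtin", fallback=True)
    layers = _layering(g)
    by_layer: dict[int, list[str]] = {}
    for n, layer in layers.items():
        by_layer.setdefault(layer, []).append(n)
    for layer in by_layer.values():
        layer.sort()

    # barycenter ordering sweeps (deterministic, fixed pass count)
    pos_in_layer = {n: i for layer in by_layer.values()
                    for i, n in enumerate(layer)}
    layer_keys = sorted(by_layer)
    for _ in range(4):
        for keys, neighbors in ((layer_keys, g.predecessors),
                                (reversed(layer_keys), g.successors)):
            for lk in keys:
                def bary(n):
                    ns = [pos_in_layer[m] for m in neighbors(n)
                          if m in pos_in_layer]
                    return (sum(ns) / len(ns)) if ns else pos_in_layer[n]
                by_layer[lk].sort(key=lambda n: (bary(n), n))
                for i, n in enumerate(by_layer[lk]):
                    pos_in_layer[n] = i

    coords: dict[str, tuple[float, float]] = {}
    for lk in layer_keys:
        for i, n in enumerate(by_layer[lk]):
            along = MARGIN + lk * LAYER_SEP
            across = MARGIN + i * NODE_SEP
            coords[n] = (across, along) if orientation == "TB" \
                else (along, across)
    xs = [c[0] for c in coords.values()]
    ys = [c[1] for c in coords.values()]
    bbox = (max(xs) + MARGIN, max(ys) + MARGIN)
    return LayoutResult(coordinates=coords, bounding_box=bbox,
                        engine="builtin", fallback=True)


def layout_dot(network: MetabolicNetwork, orientation: str = "TB",
               engine: str = "auto") -> LayoutResult:
    """Hierarchical coordinates for every node.

    ``engine="auto"`` uses graphviz ``dot`` when present on PATH and the
    deterministic built-in layered layout otherwise; ``"dot"`` demands
    the external engine (warning + fallback if absent); ``"builtin"``
    always uses the internal one.
    """
    network.validate()
    if engine not in ("auto", "dot", "builtin"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine in ("auto", "dot"):
        if _dot_available():
            return _layout_with_dot(network, orientation)
        if engine == "dot":
            warnings.warn("graphviz 'dot' not found; using built-in "
                          "layered layout", stacklevel=2)
    return _builtin_layout(network, orientation)
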