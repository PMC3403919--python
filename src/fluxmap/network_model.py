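"""Bipartite metabolite-reaction graph model and standard-format I/O.

Metabolic reactions are hypergraph-like: one reaction touches several
metabolites.  The standard graph encoding adds one *reaction node* per
reaction, labeled with the reaction name, and connects every participating
metabolite to it — reactants point into the reaction node, products point
out.  Every edge carries the stoichiometric coefficient of its metabolite
in that reaction.

Node ids are opaque strings, stable across all operations; the user-facing
join key is always the *label*.  Metabolite nodes additionally carry a
``clone_index`` (0 for the unsplit node; 1..k after hub splitting), so a
(label, clone_index) pair identifies a metabolite node uniquely.

Supported formats: SBML Level 2/3 core subset and GML/SIF for reading,
GML/GraphML for writing.  The SIF dialect is one line per edge,
``SOURCE<TAB>interaction<TAB>TARGET`` with interaction ``rp``
(reactant → reaction) or ``pr`` (reaction → product).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .dataset_io import FluxExperiment
from .errors import (
    BipartiteInferenceError,
    EmptyNetwork,
    IOFailure,
    TemplateFormatError,
    TopologyConflict,
    ValidationError,
)

__all__ = [
    "MetabolicNetwork",
    "network_from_experiment",
    "merge_missing_reactions",
    "read_network",
    "write_network",
    "METABOLITE",
    "REACTION",
]

logger = logging.getLogger(__name__)

METABOLITE = "metabolite"
REACTION = "reaction"
# connector nodes are the temporary overlay hubs re-linking clones of a
# split metabolite; they sit outside the bipartition and carry no flux.
CONNECTOR = "connector"

PathLike = Union[str, Path]


def metabolite_id(label: str, clone: int = 0) -> str:
    return f"M::{label}::{clone}"


def reaction_id(label: str) -> str:
    return f"R::{label}"


class MetabolicNetwork:
    """Directed bipartite graph of metabolite and reaction nodes.

    Thin wrapper over :class:`networkx.DiGraph`; node data keys are
    ``kind`` (``"metabolite"``/``"reaction"``), ``label``, ``clone``
    (metabolites only) plus arbitrary scalar attributes, edge data carries
    ``stoichiometry`` plus arbitrary scalar attributes.
    """

    def __init__(self, graph: nx.DiGraph | None = None) -> None:
        self.graph: nx.DiGraph = graph if graph is not None else nx.DiGraph()

    # -- construction ------------------------------------------------------

    def add_metabolite(self, label: str, clone: int = 0, **attrs) -> str:
        nid = metabolite_id(label, clone)
        if nid not in self.graph:
            self.graph.add_node(nid, kind=METABOLITE, label=label,
                                clone=clone, **attrs)
        elif attrs:
            self.graph.nodes[nid].update(attrs)
        return nid

    def add_reaction(self, label: str, **attrs) -> str:
        nid = reaction_id(label)
        if nid not in self.graph:
            self.graph.add_node(nid, kind=REACTION, label=label, **attrs)
        elif attrs:
            self.graph.nodes[nid].update(attrs)
        return nid

    def add_edge(self, source: str, target: str,
                 stoichiometry: float = 1.0, **attrs) -> None:
        if source == target:
            raise ValidationError("self-loops are not allowed")
        self.graph.add_edge(source, target, stoichiometry=float(stoichiometry),
                            **attrs)

    # -- accessors ---------------------------------------------------------

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def label(self, node: str) -> str:
        return self.graph.nodes[node]["label"]

    def clone(self, node: str) -> int:
        return self.graph.nodes[node].get("clone", 0)

    def metabolite_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == METABOLITE]

    def reaction_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == REACTION]

    def nodes_for_label(self, label: str) -> list[str]:
        """All metabolite clone nodes for a label, ordered by clone index."""
        return sorted((n for n in self.metabolite_nodes()
                       if self.label(n) == label),
                      key=self.clone)

    def reaction_node(self, label: str) -> str | None:
        nid = reaction_id(label)
        return nid if nid in self.graph else None

    def reaction_labels(self) -> list[str]:
        return [self.label(n) for n in self.reaction_nodes()]

    def metabolite_labels(self) -> list[str]:
        return sorted({self.label(n) for n in self.metabolite_nodes()})

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any structural invariant fails."""
        seen_met: set[tuple[str, int]] = set()
        seen_rxn: set[str] = set()
        for n, d in self.graph.nodes(data=True):
            kind = d.get("kind")
            if kind not in (METABOLITE, REACTION, CONNECTOR):
                raise ValidationError(f"node {n!r} has kind {kind!r}")
            if not d.get("label"):
                raise ValidationError(f"node {n!r} has no label")
            if kind == METABOLITE:
                key = (d["label"], d.get("clone", 0))
                if key in seen_met:
                    raise ValidationError(
                        f"duplicate metabolite (label, clone): {key}")
                seen_met.add(key)
            else:
                if d["label"] in seen_rxn:
                    raise ValidationError(
                        f"duplicate reaction label {d['label']!r}")
                seen_rxn.add(d["label"])
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop at {u!r}")
            if CONNECTOR in (self.kind(u), self.kind(v)):
                if not d.get("overlay"):
                    raise ValidationError(
                        f"edge {u!r}->{v!r} touches a connector but is not "
                        f"flagged as overlay")
                continue
            if {self.kind(u), self.kind(v)} != {METABOLITE, REACTION}:
                raise ValidationError(
                    f"edge {u!r}->{v!r} does not cross the bipartition")
            s = d.get("stoichiometry")
            if not (isinstance(s, (int, float)) and math.isfinite(s)
                    and s > 0):
                raise ValidationError(
                    f"edge {u!r}->{v!r} has stoichiometry {s!r}")

    # -- comparison / copy -------------------------------------------------

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(self.graph.copy())

    def graph_equal(self, other: "MetabolicNetwork") -> bool:
        """Exact equality of node sets, edge sets and all attributes."""
        g, h = self.graph, other.graph
        if set(g.nodes) != set(h.nodes) or set(g.edges) != set(h.edges):
            return False
        for n in g.nodes:
            if dict(g.nodes[n]) != dict(h.nodes[n]):
                return False
        for e in g.edges:
            if dict(g.edges[e]) != dict(h.edges[e]):
                return False
        return True

    def __len__(self) -> int:
        return len(self.graph)


# ---------------------------------------------------------------------------
# Construction from an experiment
# ---------------------------------------------------------------------------

def _add_reaction_from_equation(net: MetabolicNetwork, rxn) -> None:
    rnode = net.add_reaction(rxn.name)
    for label, s in rxn.reactants:
        mnode = _node_for_existing_label(net, label)
        net.add_edge(mnode, rnode, stoichiometry=s)
    for label, s in rxn.products:
        mnode = _node_for_existing_label(net, label)
        net.add_edge(rnode, mnode, stoichiometry=s)


def _node_for_existing_label(net: MetabolicNetwork, label: str) -> str:
    clones = net.nodes_for_label(label)
    if clones:
        return clones[0]
    return net.add_metabolite(label)


def network_from_experiment(experiment: FluxExperiment) -> MetabolicNetwork:
    """Build the bipartite network of all template reactions.

    One reaction node per equation, one metabolite node (clone 0) per
    distinct label; reactant edges point metabolite → reaction, product
    edges reaction → metabolite, each carrying its stoichiometry.
    """
    experiment.validate()
    if not experiment.reactions:
        raise EmptyNetwork("experiment declares no reactions")
    net = MetabolicNetwork()
    for label in experiment.metabolite_labels():
        net.add_metabolite(label)
    for rxn in experiment.reactions:
        _add_reaction_from_equation(net, rxn)
    net.validate()
    return net


def merge_missing_reactions(network: MetabolicNetwork,
                            experiment: FluxExperiment
                            ) -> tuple[MetabolicNetwork, dict]:
    """Add template reactions absent from the network (matched by label).

    Returns ``(new_network, report)`` where the report lists added
    reaction and metabolite labels.  Reactions already present must have
    the same reactant/product label sets, otherwise
    :class:`TopologyConflict` is raised.
    """
    network.validate()
    result = network.copy()
    added_reactions: list[str] = []
    added_metabolites: list[str] = []
    for rxn in experiment.reactions:
        rnode = result.reaction_node(rxn.name)
        if rnode is not None:
            have_reactants = {result.label(u)
                              for u in result.graph.predecessors(rnode)}
            have_products = {result.label(v)
                             for v in result.graph.successors(rnode)}
            want_reactants = {lab for lab, _ in rxn.reactants}
            want_products = {lab for lab, _ in rxn.products}
            if (have_reactants, have_products) != \
                    (want_reactants, want_products):
                raise TopologyConflict(
                    f"reaction {rxn.name!r} exists with different topology: "
                    f"has {sorted(have_reactants)} -> {sorted(have_products)}, "
                    f"template says {sorted(want_reactants)} -> "
                    f"{sorted(want_products)}")
            continue
        existing_labels = {result.label(n)
                           for n in result.metabolite_nodes()}
        for label in sorted(rxn.labels - existing_labels):
            added_metabolites.append(label)
        _add_reaction_from_equation(result, rxn)
        added_reactions.append(rxn.name)
    result.validate()
    report = {"added_reactions": added_reactions,
              "added_metabolites": added_metabolites}
    return result, report


# ---------------------------------------------------------------------------
# GML
# ---------------------------------------------------------------------------

def _gml_escape(text: str) -> str:
    out = []
    for ch in text:
        if ch == "&":
            out.append("&amp;")
        elif ch == '"':
            out.append("&quot;")
        elif ord(ch) > 126:
            out.append(f"&#{ord(ch)};")
        else:
            out.append(ch)
    return "".join(out)


def _gml_value(value) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return f'"{_gml_escape(str(value))}"'


def _write_gml(network: MetabolicNetwork, path: PathLike) -> None:
    ids = {n: i for i, n in enumerate(network.graph.nodes)}
    lines = ["graph [", "  directed 1"]
    for n, data in network.graph.nodes(data=True):
        lines.append("  node [")
        lines.append(f"    id {ids[n]}")
        lines.append(f"    label {_gml_value(data['label'])}")
        for key, value in data.items():
            if key == "label":
                continue
            lines.append(f"    {key} {_gml_value(value)}")
        lines.append("  ]")
    for u, v, data in network.graph.edges(data=True):
        lines.append("  edge [")
        lines.append(f"    source {ids[u]}")
        lines.append(f"    target {ids[v]}")
        for key, value in data.items():
            lines.append(f"    {key} {_gml_value(value)}")
        lines.append("  ]")
    lines.append("]")
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


def _network_from_plain_graph(g: nx.Graph | nx.DiGraph,
                              reaction_labels: Iterable[str] | None = None
                              ) -> MetabolicNetwork:
    """Classify raw nodes into metabolites/reactions and rebuild the model.

    Nodes carrying ``kind`` are taken at face value.  Otherwise a
    two-coloring of each connected component is attempted and the reaction
    side is decided by matching ``reaction_labels``; an ambiguous or
    non-bipartite graph is an error, never a guess.
    """
    known = set(reaction_labels) if reaction_labels else set()
    kinds: dict = {}
    for n, d in g.nodes(data=True):
        k = d.get("kind")
        if k in (METABOLITE, REACTION):
            kinds[n] = k
    if len(kinds) < len(g):
        undirected = g.to_undirected(as_view=True)
        if not nx.is_bipartite(undirected):
            raise BipartiteInferenceError(
                "graph is not bipartite; cannot classify nodes")
        for component in nx.connected_components(undirected):
            sub = undirected.subgraph(component)
            side0, side1 = nx.bipartite.sets(sub)
            anchored = None
            for side, other in ((side0, side1), (side1, side0)):
                if any(kinds.get(n) == REACTION for n in side) or \
                        any(g.nodes[n].get("label", n) in known
                            for n in side):
                    anchored = (side, other)
                    break
                if any(kinds.get(n) == METABOLITE for n in side):
                    anchored = (other, side)
                    break
            if anchored is None:
                raise BipartiteInferenceError(
                    "cannot decide which bipartition side holds reactions "
                    f"for component {sorted(map(str, component))[:5]}...")
            rxn_side, met_side = anchored
            for n in rxn_side:
                kinds.setdefault(n, REACTION)
            for n in met_side:
                kinds.setdefault(n, METABOLITE)

    net = MetabolicNetwork()
    id_map: dict = {}
    for n, d in g.nodes(data=True):
        label = str(d.get("label", n))
        extra = {k: v for k, v in d.items()
                 if k not in ("kind", "label", "clone")}
        if kinds[n] == METABOLITE:
            id_map[n] = net.add_metabolite(label, clone=int(d.get("clone", 0)),
                                           **extra)
        else:
            id_map[n] = net.add_reaction(label, **extra)
    for u, v, d in g.edges(data=True):
        s = d.get("stoichiometry")
        if s is None:
            logger.warning("edge %s->%s has no stoichiometry; defaulting to 1",
                           u, v)
            s = 1.0
        extra = {k: v for k, v in d.items() if k != "stoichiometry"}
        net.add_edge(id_map[u], id_map[v], stoichiometry=float(s), **extra)
    net.validate()
    return net


def _read_gml(path: PathLike,
              reaction_labels: Iterable[str] | None) -> MetabolicNetwork:
    g = nx.read_gml(path, label=None)
    if not g.is_directed():
        g = g.to_directed()
    return _network_from_plain_graph(g, reaction_labels)


# ---------------------------------------------------------------------------
# SBML (Level 2/3 core subset, read with lxml)
# ---------------------------------------------------------------------------

def _read_sbml(path: PathLike) -> MetabolicNetwork:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise IOFailure(f"cannot parse SBML {path!r}: {exc}") from exc
    root = tree.getroot()

    def local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    net = MetabolicNetwork()
    species_ids: set[str] = set()
    for sp in root.iter():
        if local(sp.tag) != "species":
            continue
        sid = sp.get("id")
        if sid is None:
            continue
        attrs = {}
        if sp.get("name"):
            attrs["name"] = sp.get("name")
        if sp.get("compartment"):
            attrs["compartment"] = sp.get("compartment")
        net.add_metabolite(sid, **attrs)
        species_ids.add(sid)

    n_reactions = 0
    for rx in root.iter():
        if local(rx.tag) != "reaction":
            continue
        rid = rx.get("id")
        if rid is None:
            continue
        attrs = {}
        if rx.get("name"):
            attrs["name"] = rx.get("name")
        if rx.get("reversible") is not None:
            # recorded for provenance; mapping direction is data-driven
            attrs["reversible"] = int(rx.get("reversible") == "true")
        rnode = net.add_reaction(rid, **attrs)
        n_reactions += 1
        for child in rx:
            role = local(child.tag)
            if role not in ("listOfReactants", "listOfProducts"):
                if role not in ("listOfModifiers", "kineticLaw", "notes",
                                "annotation"):
                    logger.warning("SBML: ignoring %s in reaction %s",
                                   role, rid)
                continue
            for ref in child:
                if local(ref.tag) != "speciesReference":
                    continue
                species = ref.get("species")
                if species not in species_ids:
                    net.add_metabolite(species)
                    species_ids.add(species)
                stoich = float(ref.get("stoichiometry", "1"))
                mnode = metabolite_id(species, 0)
                if role == "listOfReactants":
                    net.add_edge(mnode, rnode, stoichiometry=stoich)
                else:
                    net.add_edge(rnode, mnode, stoichiometry=stoich)
    if n_reactions == 0 and not species_ids:
        raise TemplateFormatError(f"{path!r}: no SBML species or reactions")
    net.validate()
    return net


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def _read_sif(path: PathLike) -> MetabolicNetwork:
    net = MetabolicNetwork()
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot read {path!r}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TemplateFormatError(
                f"{path}:{lineno}: expected SOURCE<TAB>interaction<TAB>TARGET")
        source, interaction, target = (p.strip() for p in parts)
        if interaction == "rp":
            m = net.add_metabolite(source)
            r = net.add_reaction(target)
            net.add_edge(m, r, stoichiometry=1.0)
        elif interaction == "pr":
            r = net.add_reaction(source)
            m = net.add_metabolite(target)
            net.add_edge(r, m, stoichiometry=1.0)
        else:
            raise BipartiteInferenceError(
                f"{path}:{lineno}: unknown interaction {interaction!r} "
                f"(expected 'rp' or 'pr')")
    logger.info("SIF carries no stoichiometries; all edges default to 1")
    net.validate()
    return net


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def _write_graphml(network: MetabolicNetwork, path: PathLike) -> None:
    g = nx.DiGraph()
    for n, d in network.graph.nodes(data=True):
        g.add_node(n, **d)
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(u, v, **d)
    nx.write_graphml(g, str(path), named_key_ids=True)


def _read_graphml(path: PathLike,
                  reaction_labels: Iterable[str] | None) -> MetabolicNetwork:
    g = nx.read_graphml(str(path))
    if not g.is_directed():
        g = g.to_directed()
    return _network_from_plain_graph(g, reaction_labels)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

_READERS = {"sbml": None, "gml": None, "sif": None, "graphml": None}


def _infer_format(path: PathLike) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("xml", "sbml"):
        return "sbml"
    if suffix in _READERS:
        return suffix
    raise TemplateFormatError(f"cannot infer network format from {path!r}")


def read_network(path: PathLike, format: str | None = None,
                 reaction_labels: Iterable[str] | None = None
                 ) -> MetabolicNetwork:
    """Read a network from SBML, GML, SIF or GraphML.

    ``reaction_labels`` (e.g. the template's reaction names) anchors the
    bipartite inference for formats whose nodes carry no ``kind``.
    """
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "gml":
        return _read_gml(path, reaction_labels)
    if fmt == "sif":
        return _read_sif(path)
    if fmt == "graphml":
        return _read_graphml(path, reaction_labels)
    raise TemplateFormatError(f"unknown network format {fmt!r}")


def write_network(network: MetabolicNetwork, path: PathLike,
                  format: str | None = None) -> None:
    """Write a network (with any attached attributes) to GML or GraphML."""
    network.validate()
    fmt = format or _infer_format(path)
    try:
        if fmt == "gml":
            _write_gml(network, path)
        elif fmt == "graphml":
            _write_graphml(network, path)
        else:
            raise TemplateFormatError(f"unsupported output format {fmt!r}")
    except OSError as exc:
        raise IOFailure(f"cannot write {path!r}: {exc}") from exc
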