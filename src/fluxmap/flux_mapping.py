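"""Project one (condition, timepoint) of an experiment onto a network.

The per-edge quantity drawn as edge thickness is the *substance flux*

    f = |v| * s * w

where ``v`` is the reaction's measured flux (sign = net direction), ``s``
the stoichiometry of the metabolite in that reaction and ``w`` the
substance weight (traced atoms per molecule).  With all weights 1 this
degenerates to the mass flux ``|v| * s``.

A negative ``v`` reverses all edges incident to the reaction *within the
slice's working copy only*; the base network is never mutated, so slices
from different conditions may disagree on direction.  Reactions with a
zero flux, or with no measurement in the slice, keep all their edges
(dashed downstream) so the network topology stays visible even for
sparse flux data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .dataset_io import FluxExperiment
from .errors import CrossReferenceError, NumericError, UnmappedMeasurement
from .network_model import MetabolicNetwork, REACTION

__all__ = ["FluxMapSlice", "effective_edge_flux", "map_slice", "list_slices"]

Edge = tuple[str, str]


def effective_edge_flux(v: float, stoichiometry: float, weight: float
                        ) -> float:
    """Per-edge substance flux ``|v| * stoichiometry * weight``."""
    for x in (v, stoichiometry, weight):
        if not math.isfinite(x):
            raise NumericError(f"non-finite input to edge flux: {x!r}")
    return abs(v) * stoichiometry * weight


@dataclass
class FluxMapSlice:
    """One condition/timepoint mapped onto a (direction-adapted) network.

    ``network`` is a working copy whose edges already point in the net
    flux direction.  Every edge of the base network appears either in
    ``edge_flux`` (measured, value >= 0) or in ``zero_edges`` (zero or
    missing measurement, rendered dashed).
    """

    network: MetabolicNetwork
    condition: str
    timepoint: str
    edge_flux: dict[Edge, float] = field(default_factory=dict)
    reaction_flux: dict[str, float] = field(default_factory=dict)
    reaction_quality: dict[str, float] = field(default_factory=dict)
    zero_edges: set[Edge] = field(default_factory=set)
    weights: dict[str, int] = field(default_factory=dict)

    def incident_edges(self, reaction_node: str) -> list[Edge]:
        g = self.network.graph
        return list(g.in_edges(reaction_node)) + \
            list(g.out_edges(reaction_node))

    def flux_of(self, edge: Edge) -> float:
        return self.edge_flux.get(edge, 0.0)

    def owning_reaction(self, edge: Edge) -> str:
        u, v = edge
        return u if self.network.kind(u) == REACTION else v

    def validate(self) -> None:
        all_edges = set(self.network.graph.edges)
        covered = set(self.edge_flux) | self.zero_edges
        if covered != all_edges:
            raise AssertionError(
                "slice does not cover the network edge set exactly")
        for e, f in self.edge_flux.items():
            if f < 0:
                raise AssertionError(f"negative edge flux on {e}")
            if f > 0 and e in self.zero_edges:
                raise AssertionError(f"edge {e} both fluxed and zero")


def _reverse_edges(net: MetabolicNetwork, reaction_node: str) -> None:
    g = net.graph
    incident = list(g.in_edges(reaction_node, data=True)) + \
        list(g.out_edges(reaction_node, data=True))
    for u, v, _ in incident:
        g.remove_edge(u, v)
    for u, v, data in incident:
        g.add_edge(v, u, **data)


def map_slice(network: MetabolicNetwork, experiment: FluxExperiment,
              condition: str, timepoint: str) -> FluxMapSlice:
    """Map the measurements of one (condition, timepoint) onto ``network``.

    Preconditions: the condition and timepoint are declared in the
    experiment, and the network already contains every measured reaction
    (run :func:`~fluxmap.network_model.merge_missing_reactions` first if
    not).
    """
    if condition not in experiment.conditions:
        raise CrossReferenceError(f"undeclared condition {condition!r}")
    if timepoint not in experiment.timepoints:
        raise CrossReferenceError(f"undeclared timepoint {timepoint!r}")

    present = {network.label(n) for n in network.reaction_nodes()}
    missing = {m.reaction_name for m in experiment.measurements
               if m.condition == condition and m.timepoint == timepoint
               and m.reaction_name not in present}
    if missing:
        raise UnmappedMeasurement(missing)

    working = network.copy()
    slc = FluxMapSlice(network=working, condition=condition,
                       timepoint=timepoint,
                       weights=dict(experiment.substance_weights))

    for rnode in sorted(working.reaction_nodes()):
        rlabel = working.label(rnode)
        m = experiment.measurement_for(rlabel, condition, timepoint)
        if m is not None:
            slc.reaction_flux[rnode] = m.flux_value
            if m.quality is not None:
                slc.reaction_quality[rnode] = m.quality
        v = m.flux_value if m is not None else None
        if v is not None and v < 0:
            _reverse_edges(working, rnode)
        if v:  # nonzero measured flux
            g = working.graph
            for u, w_ in slc.incident_edges(rnode):
                met = u if u != rnode else w_
                s = g.edges[u, w_]["stoichiometry"]
                slc.edge_flux[(u, w_)] = effective_edge_flux(
                    v, s, experiment.weight(working.label(met)))
        else:
            slc.zero_edges.update(slc.incident_edges(rnode))
    slc.validate()
    return slc


def list_slices(experiment: FluxExperiment) -> list[tuple[str, str]]:
    """All (condition, timepoint) pairs, condition-major, declaration order."""
    experiment.validate()
    return [(c, t) for c in experiment.conditions
            for t in experiment.timepoints]
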