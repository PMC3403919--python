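"""Slice mapping: edge flux computation, direction adaptation, zero fluxes."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_experiment
from fluxmap import fixtures as fx
from fluxmap.errors import (
    CrossReferenceError,
    NumericError,
    UnmappedMeasurement,
)
from fluxmap.flux_mapping import (
    effective_edge_flux,
    list_slices,
    map_slice,
)
from fluxmap.network_model import network_from_experiment


class TestEffectiveEdgeFlux:
    @pytest.mark.parametrize("v,s,w,expected", [
        (2.0, 1.0, 1, 2.0),     # mass-flux convention: weight 1
        (1.5, 2.0, 6, 18.0),    # hand multiplication
        (-3.0, 1.0, 2, 6.0),    # sign handled by direction, not magnitude
        (0.0, 5.0, 3, 0.0),
        (1.0, 0.5, 0, 0.0),     # zero-weight metabolite carries no atoms
    ])
    def test_values(self, v, s, w, expected):
        assert effective_edge_flux(v, s, w) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(NumericError):
            effective_edge_flux(bad, 1.0, 1)

    @given(st.floats(-1e6, 1e6), st.floats(0.01, 100),
           st.integers(0, 12))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_even_in_v(self, v, s, w):
        f = effective_edge_flux(v, s, w)
        assert f >= 0
        assert f == effective_edge_flux(-v, s, w)


class TestMapSlice:
    def test_negative_flux_reverses_edges(self):
        exp = make_experiment([("r1", "A -> B")], {"A": 1, "B": 1},
                              {"r1": -1.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        rnode = slc.network.reaction_node("r1")
        a = slc.network.nodes_for_label("A")[0]
        b = slc.network.nodes_for_label("B")[0]
        assert set(slc.network.graph.edges) == {(b, rnode), (rnode, a)}
        assert slc.edge_flux[(b, rnode)] == 1.0
        assert slc.edge_flux[(rnode, a)] == 1.0

    def test_zero_flux_edges_kept_as_zero(self, chain_experiment):
        exp = make_experiment([("r1", "A -> B"), ("r2", "B -> C")],
                              {"A": 1, "B": 1, "C": 1},
                              {"r1": 1.0, "r2": 0.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        rnode = slc.network.reaction_node("r2")
        incident = set(slc.incident_edges(rnode))
        assert incident <= slc.zero_edges
        assert len(slc.network.graph.edges) == len(net.graph.edges)

    def test_unmeasured_reaction_is_zero_flux_not_error(self):
        exp = make_experiment([("r1", "A -> B"), ("r2", "B -> C")],
                              {"A": 1, "B": 1, "C": 1},
                              {"r1": 1.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        rnode = slc.network.reaction_node("r2")
        assert set(slc.incident_edges(rnode)) <= slc.zero_edges

    def test_deterministic(self, seed_toy):
        a = map_slice(seed_toy.network, seed_toy.experiment, "A", "t0")
        b = map_slice(seed_toy.network, seed_toy.experiment, "A", "t0")
        assert a.edge_flux == b.edge_flux
        assert a.zero_edges == b.zero_edges
        assert set(a.network.graph.edges) == set(b.network.graph.edges)

    def test_undeclared_slice_rejected(self, seed_toy):
        with pytest.raises(CrossReferenceError):
            map_slice(seed_toy.network, seed_toy.experiment, "Z", "t0")
        with pytest.raises(CrossReferenceError):
            map_slice(seed_toy.network, seed_toy.experiment, "A", "t9")

    def test_measurement_without_network_reaction(self, seed_toy):
        net = seed_toy.network.copy()
        net.graph.remove_node(net.reaction_node("glyc"))
        with pytest.raises(UnmappedMeasurement, match="glyc"):
            map_slice(net, seed_toy.experiment, "A", "t0")

    def test_topology_preserved_on_all_slices(self, fba_toy):
        n_edges = fba_toy.network.graph.number_of_edges()
        for cond, tp in list_slices(fba_toy.experiment):
            slc = map_slice(fba_toy.network, fba_toy.experiment, cond, tp)
            assert slc.network.graph.number_of_edges() == n_edges
            assert set(slc.edge_flux) | slc.zero_edges == \
                set(slc.network.graph.edges)

    def test_double_negation_is_identity(self, hub_experiment, hub_network):
        import copy
        flipped = copy.deepcopy(hub_experiment)
        flipped.measurements = [
            type(m)(m.reaction_name, m.condition, m.timepoint,
                    -m.flux_value, m.quality)
            for m in flipped.measurements]
        base = map_slice(hub_network, hub_experiment, "C1", "T1")
        double = copy.deepcopy(flipped)
        double.measurements = [
            type(m)(m.reaction_name, m.condition, m.timepoint,
                    -m.flux_value, m.quality)
            for m in flipped.measurements]
        again = map_slice(hub_network, double, "C1", "T1")
        assert set(again.network.graph.edges) == \
            set(base.network.graph.edges)
        assert again.edge_flux == base.edge_flux
        # single negation reverses every measured edge
        once = map_slice(hub_network, flipped, "C1", "T1")
        for (u, v), f in base.edge_flux.items():
            assert once.edge_flux[(v, u)] == f

    @given(st.floats(0.001, 1000))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_measurements(self, c):
        bundle = fx.generate(fx.FixtureSpec(topology="branched",
                                            n_reactions=6, seed=9))
        import copy
        scaled = copy.deepcopy(bundle.experiment)
        scaled.measurements = [
            type(m)(m.reaction_name, m.condition, m.timepoint,
                    m.flux_value * c, m.quality)
            for m in scaled.measurements]
        base = map_slice(bundle.network, bundle.experiment, "C1", "T1")
        multiplied = map_slice(bundle.network, scaled, "C1", "T1")
        for e, f in base.edge_flux.items():
            assert multiplied.edge_flux[e] == pytest.approx(c * f,
                                                            rel=1e-12)

    def test_mass_flux_degenerate_case(self):
        exp = make_experiment([("r1", "A -> B"), ("r2", "B -> C")],
                              {"A": 1, "B": 1, "C": 1},
                              {"r1": 2.5, "r2": 2.5})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        assert set(slc.edge_flux.values()) == {2.5}


class TestListSlices:
    def test_cartesian_condition_major(self):
        exp = make_experiment([("r1", "A -> B")], {"A": 1, "B": 1},
                              {"r1": 1.0},
                              conditions=("c2", "c1"),
                              timepoints=("late", "early", "mid"))
        assert list_slices(exp) == [
            ("c2", "late"), ("c2", "early"), ("c2", "mid"),
            ("c1", "late"), ("c1", "early"), ("c1", "mid")]

    def test_single_pair(self, chain_experiment):
        assert list_slices(chain_experiment) == [("C1", "T1")]
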