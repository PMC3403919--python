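"""Reaction and metabolite balance: hand oracles, properties, reporting."""

import copy

import pytest

from conftest import make_experiment
from fluxmap import fixtures as fx
from fluxmap.balance_validation import (
    summarize_report,
    validate_metabolites,
    validate_reactions,
    validate_slice,
)
from fluxmap.flux_mapping import map_slice
from fluxmap.layout_interaction import split_label
from fluxmap.network_model import network_from_experiment


def brute_force_sums(slc):
    """Independent residual oracle: iterate the raw edge incidence list
    and accumulate per-node in/out sums from edge_flux alone."""
    inflow, outflow = {}, {}
    for (u, v), f in slc.edge_flux.items():
        outflow[u] = outflow.get(u, 0.0) + f
        inflow[v] = inflow.get(v, 0.0) + f
    return inflow, outflow


class TestReactionBalance:
    def test_sucrose_cleavage_balanced(self, sucrose_experiment):
        net = network_from_experiment(sucrose_experiment)
        slc = map_slice(net, sucrose_experiment, "C1", "T1")
        (entry,) = validate_reactions(slc).reaction_entries
        assert entry.inflow == pytest.approx(12.0)
        assert entry.outflow == pytest.approx(12.0)
        assert entry.balanced

    def test_glued_stoichiometry_detected(self):
        # "2Suc" instead of "2 Suc": the bogus label carries sucrose's
        # weight but only stoichiometry 1, so carbon no longer balances
        exp = make_experiment([("inv", "2Suc -> Fru + Glc")],
                              {"2Suc": 6, "Fru": 6, "Glc": 6},
                              {"inv": 1.0})
        correct = make_experiment([("inv", "2 Suc -> Fru + Glc")],
                                  {"Suc": 6, "Fru": 6, "Glc": 6},
                                  {"inv": 1.0})
        for experiment, expect_balanced in ((exp, False), (correct, True)):
            net = network_from_experiment(experiment)
            slc = map_slice(net, experiment, "C1", "T1")
            (entry,) = validate_reactions(slc).reaction_entries
            assert entry.balanced is expect_balanced

    def test_mass_flux_condensation_unbalanced(self):
        exp = make_experiment([("r", "A + B -> C")],
                              {"A": 1, "B": 1, "C": 1},
                              {"r": 2.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        (entry,) = validate_reactions(slc).reaction_entries
        assert entry.inflow == pytest.approx(4.0)
        assert entry.outflow == pytest.approx(2.0)
        assert not entry.balanced

    def test_zero_flux_reaction_gets_structural_check(self):
        exp = make_experiment([("r", "A -> B")], {"A": 2, "B": 3},
                              {"r": 0.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        (entry,) = validate_reactions(slc).reaction_entries
        assert entry.balanced          # 0 = 0 numerically
        assert entry.structural_warning  # but 2 != 3 atoms structurally
        assert entry.structural_residual == pytest.approx(-1.0)

    def test_report_covers_each_reaction_once(self, fba_toy):
        slc = map_slice(fba_toy.network, fba_toy.experiment, "aerobic", "t0")
        report = validate_reactions(slc)
        labels = [e.label for e in report.reaction_entries]
        assert sorted(labels) == sorted(set(labels))
        assert set(labels) == set(fba_toy.network.reaction_labels())

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_agreement(self, seed):
        bundle = fx.generate(fx.FixtureSpec(
            topology=("chain", "branched", "cycle")[seed % 3],
            n_reactions=5 + seed, quality_mode="confidence", seed=seed))
        slc = map_slice(bundle.network, bundle.experiment, "C1", "T1")
        report = validate_slice(slc, bundle.external_labels)
        inflow, outflow = brute_force_sums(slc)
        for entry in report.reaction_entries:
            rnode = slc.network.reaction_node(entry.label)
            assert entry.inflow == inflow.get(rnode, 0.0)
            assert entry.outflow == outflow.get(rnode, 0.0)
            assert entry.residual == entry.inflow - entry.outflow

    def test_scale_invariance_of_verdict(self):
        bundle = fx.generate(fx.FixtureSpec(topology="branched",
                                            n_reactions=7, seed=13))
        scaled = copy.deepcopy(bundle.experiment)
        scaled.measurements = [
            type(m)(m.reaction_name, m.condition, m.timepoint,
                    m.flux_value * 1e6, m.quality)
            for m in scaled.measurements]
        flags = lambda exp: [
            e.balanced for e in validate_reactions(
                map_slice(bundle.network, exp, "C1", "T1")).reaction_entries]
        assert flags(bundle.experiment) == flags(scaled)


class TestMetaboliteBalance:
    def test_linear_chain_termini(self, chain_experiment):
        net = network_from_experiment(chain_experiment)
        slc = map_slice(net, chain_experiment, "C1", "T1")
        report = validate_metabolites(slc)
        by_label = {e.label: e for e in report.metabolite_entries}
        assert by_label["B"].balanced
        assert not by_label["A"].balanced
        assert not by_label["C"].balanced
        exempted = validate_metabolites(slc, {"A", "C"})
        assert exempted.failed_metabolites() == []

    def test_untouched_metabolite_trivially_balanced(self):
        exp = make_experiment([("r1", "A -> B"), ("r2", "C -> D")],
                              {"A": 1, "B": 1, "C": 1, "D": 1},
                              {"r1": 1.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        by_label = {e.label: e
                    for e in validate_metabolites(slc).metabolite_entries}
        assert by_label["C"].production == 0.0
        assert by_label["C"].consumption == 0.0
        assert by_label["C"].balanced

    def test_split_clones_sum_like_unsplit(self, hub_experiment,
                                           hub_network):
        split_net = split_label(hub_network, "ATP_c")
        base = map_slice(hub_network, hub_experiment, "C1", "T1")
        split = map_slice(split_net, hub_experiment, "C1", "T1")
        base_entries = {e.label: e for e in
                        validate_metabolites(base).metabolite_entries}
        split_entries = {e.label: e for e in
                         validate_metabolites(split).metabolite_entries}
        assert base_entries.keys() == split_entries.keys()
        for label, e in base_entries.items():
            assert split_entries[label].production == e.production
            assert split_entries[label].consumption == e.consumption


class TestSummary:
    def test_all_balanced_status_zero(self, seed_toy):
        slc = map_slice(seed_toy.network, seed_toy.experiment, "A", "t0")
        report = validate_slice(slc, seed_toy.external_labels)
        status, text, payload = summarize_report(report)
        assert status == 0
        assert payload["unbalanced_reactions"] == []
        assert "balanced" in text

    def test_injected_typo_ranked_first(self):
        bundle = fx.generate(fx.FixtureSpec(
            topology="chain", n_reactions=6, seed=3,
            corruption="wrong_stoichiometry"))
        slc = map_slice(bundle.network, bundle.experiment, "C1", "T1")
        report = validate_reactions(slc)
        status, _, payload = summarize_report(report)
        assert status == 3
        assert payload["unbalanced_reactions"][0]["label"] == \
            bundle.corruption[1]

    def test_equal_residuals_tie_break_lexicographic(self):
        exp = make_experiment(
            [("b_rxn", "A + X -> B"), ("a_rxn", "C + X -> D")],
            {"A": 1, "B": 1, "C": 1, "D": 1, "X": 1},
            {"b_rxn": 1.0, "a_rxn": 1.0})
        net = network_from_experiment(exp)
        slc = map_slice(net, exp, "C1", "T1")
        report = validate_reactions(slc)
        _, _, payload = summarize_report(report)
        labels = [e["label"] for e in payload["unbalanced_reactions"]]
        assert labels == ["a_rxn", "b_rxn"]
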