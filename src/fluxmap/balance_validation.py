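"""Reaction- and metabolite-level flux balance checks for a mapped slice.

A reaction is balanced when the summed substance flux entering its node
equals the summed substance flux leaving it — with ``f = |v| * s * w``
this is exactly atom conservation, so an unbalanced reaction almost
always points at a template defect: a misspelled substance name, a
stoichiometry glued to its label (``2Suc`` for ``2 Suc``), a missing
stoichiometry or a missing reactant.  In mass-flux maps (all weights 1)
reactions with unequal summed substrate and product stoichiometries can
never balance; the check is then only meaningful per metabolite.

A metabolite is balanced at steady state when its production equals its
consumption, summed over all of its clone nodes.  Boundary metabolites
(uptake, excretion, biomass sinks) are exempted via an explicit external
list — nothing is auto-exempted.

Validation never raises on unbalanced data; it reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .flux_mapping import FluxMapSlice
from .network_model import METABOLITE

__all__ = [
    "ReactionBalanceEntry",
    "MetaboliteBalanceEntry",
    "BalanceReport",
    "validate_reactions",
    "validate_metabolites",
    "validate_slice",
    "summarize_report",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ReactionBalanceEntry:
    label: str
    inflow: float
    outflow: float
    residual: float
    balanced: bool
    # zero-flux reactions get a v-independent structural atom check
    # (sum s*w per side); a mismatch is a warning, not a failure.
    structural_warning: bool = False
    structural_residual: float = 0.0


@dataclass(frozen=True)
class MetaboliteBalanceEntry:
    label: str
    production: float
    consumption: float
    residual: float
    balanced: bool
    exempt: bool = False


@dataclass
class BalanceReport:
    """Residuals and flags for one (condition, timepoint) slice."""

    slice_id: tuple[str, str]
    tolerance: float = DEFAULT_TOLERANCE
    reaction_entries: list[ReactionBalanceEntry] = field(default_factory=list)
    metabolite_entries: list[MetaboliteBalanceEntry] = field(
        default_factory=list)

    def failed_reactions(self) -> list[ReactionBalanceEntry]:
        return _sorted_failures(
            [e for e in self.reaction_entries if not e.balanced])

    def failed_metabolites(self) -> list[MetaboliteBalanceEntry]:
        return _sorted_failures(
            [e for e in self.metabolite_entries
             if not e.balanced and not e.exempt])

    def structural_warnings(self) -> list[ReactionBalanceEntry]:
        return [e for e in self.reaction_entries if e.structural_warning]

    @property
    def all_balanced(self) -> bool:
        return not self.failed_reactions() and not self.failed_metabolites()


def _sorted_failures(entries):
    return sorted(entries, key=lambda e: (-abs(e.residual), e.label))


def _is_balanced(lhs: float, rhs: float, tolerance: float) -> bool:
    return abs(lhs - rhs) <= tolerance * max(lhs, rhs, 1.0)


def validate_reactions(slc: FluxMapSlice,
                       tolerance: float = DEFAULT_TOLERANCE,
                       report: BalanceReport | None = None) -> BalanceReport:
    """Check inflow == outflow at every reaction node of the slice.

    Zero-flux reactions (no measurement, or v = 0) report inflow =
    outflow = 0 and instead get the structural atom check
    ``sum(s*w) reactants == sum(s*w) products``; a structural mismatch is
    flagged as a warning so that 0 = 0 cannot hide a template typo.
    """
    if report is None:
        report = BalanceReport(slice_id=(slc.condition, slc.timepoint),
                               tolerance=tolerance)
    g = slc.network.graph
    for rnode in sorted(slc.network.reaction_nodes(),
                        key=slc.network.label):
        label = slc.network.label(rnode)
        measured = bool(slc.reaction_flux.get(rnode))
        if measured:
            inflow = sum(slc.flux_of(e) for e in g.in_edges(rnode))
            outflow = sum(slc.flux_of(e) for e in g.out_edges(rnode))
            report.reaction_entries.append(ReactionBalanceEntry(
                label=label, inflow=inflow, outflow=outflow,
                residual=inflow - outflow,
                balanced=_is_balanced(inflow, outflow, tolerance)))
        else:
            s_res = _structural_residual(slc, rnode)
            warn = s_res is not None and abs(s_res) > tolerance
            report.reaction_entries.append(ReactionBalanceEntry(
                label=label, inflow=0.0, outflow=0.0, residual=0.0,
                balanced=True, structural_warning=warn,
                structural_residual=s_res if s_res is not None else 0.0))
    return report


def _structural_residual(slc: FluxMapSlice, rnode: str) -> float | None:
    """sum(s*w) over reactant side minus product side; None if a weight
    is unknown (network-only metabolite)."""
    g = slc.network.graph
    total = 0.0
    for u, v in slc.incident_edges(rnode):
        met = u if u != rnode else v
        label = slc.network.label(met)
        if label not in slc.weights:
            return None
        contrib = g.edges[u, v]["stoichiometry"] * slc.weights[label]
        total += contrib if v == rnode else -contrib
    return total


def validate_metabolites(slc: FluxMapSlice,
                         external_labels: set[str] | frozenset[str] = frozenset(),
                         tolerance: float = DEFAULT_TOLERANCE,
                         report: BalanceReport | None = None) -> BalanceReport:
    """Check steady-state production == consumption per metabolite label.

    Sums run over all clones of a label, so hub splitting cannot change
    the verdict.  Labels in ``external_labels`` are marked exempt and
    never counted as failures.
    """
    if report is None:
        report = BalanceReport(slice_id=(slc.condition, slc.timepoint),
                               tolerance=tolerance)
    g = slc.network.graph
    external = set(external_labels)
    by_label: dict[str, list[str]] = {}
    for n in slc.network.metabolite_nodes():
        by_label.setdefault(slc.network.label(n), []).append(n)
    for label in sorted(by_label):
        production = sum(slc.flux_of(e)
                         for n in by_label[label] for e in g.in_edges(n))
        consumption = sum(slc.flux_of(e)
                          for n in by_label[label] for e in g.out_edges(n))
        report.metabolite_entries.append(MetaboliteBalanceEntry(
            label=label, production=production, consumption=consumption,
            residual=production - consumption,
            balanced=_is_balanced(production, consumption, tolerance),
            exempt=label in external))
    return report


def validate_slice(slc: FluxMapSlice,
                   external_labels: set[str] | frozenset[str] = frozenset(),
                   tolerance: float = DEFAULT_TOLERANCE) -> BalanceReport:
    """Full reaction + metabolite validation of one slice."""
    report = validate_reactions(slc, tolerance)
    return validate_metabolites(slc, external_labels, tolerance, report)


def summarize_report(report: BalanceReport) -> tuple[int, str, dict]:
    """Render a report for humans and machines.

    Returns ``(status, text, payload)`` where status is 0 when everything
    is balanced and 3 when anything is not.  Failures are listed by
    descending absolute residual, ties broken lexicographically by label.
    """
    bad_rxn = report.failed_reactions()
    bad_met = report.failed_metabolites()
    status = 0 if not bad_rxn and not bad_met else 3

    lines = [f"slice condition={report.slice_id[0]!r} "
             f"timepoint={report.slice_id[1]!r} "
             f"(tolerance {report.tolerance:g})"]
    if status == 0:
        lines.append("all reactions and metabolites balanced")
    for e in bad_rxn:
        lines.append(f"UNBALANCED reaction {e.label}: "
                     f"in {e.inflow:g} out {e.outflow:g} "
                     f"residual {e.residual:g}")
    for e in bad_met:
        lines.append(f"UNBALANCED metabolite {e.label}: "
                     f"production {e.production:g} "
                     f"consumption {e.consumption:g} "
                     f"residual {e.residual:g}")
    for e in report.structural_warnings():
        lines.append(f"warning: zero-flux reaction {e.label} is structurally "
                     f"unbalanced (sum s*w residual {e.structural_residual:g})")

    payload = {
        "condition": report.slice_id[0],
        "timepoint": report.slice_id[1],
        "tolerance": report.tolerance,
        "status": status,
        "unbalanced_reactions": [
            {"label": e.label, "inflow": e.inflow, "outflow": e.outflow,
             "residual": e.residual} for e in bad_rxn],
        "unbalanced_metabolites": [
            {"label": e.label, "production": e.production,
             "consumption": e.consumption, "residual": e.residual}
            for e in bad_met],
        "structural_warnings": [
            {"label": e.label, "residual": e.structural_residual}
            for e in report.structural_warnings()],
    }
    json.dumps(payload)  # guarantee machine-readability
    return status, "\n".join(lines), payload
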