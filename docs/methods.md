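# Methods

## The flux-map model

A flux experiment is a table of per-reaction flux measurements *v*
(signed; units are whatever the experiment used — the package never
converts units) indexed by condition and timepoint, together with
reaction equations, substance weights *w* (a nonnegative integer per
metabolite: traced atoms per molecule), and optional per-measurement
quality scalars *q*.

The network is a directed bipartite graph. Reactions are hyperedges in
chemistry; the standard graph encoding inserts one reaction node per
reaction and connects each participating metabolite with an edge
carrying its stoichiometry *s*. Mapping a (condition, timepoint) slice
assigns each edge the per-edge substance flux

    f = |v| · s · w .

This product is the only per-edge quantity for which "inflow equals
outflow at the reaction node" is exactly atom conservation: a reaction
consuming one molecule of weight *w* must deliver *s·w′* atoms to its
products, so Σ s·w over reactants equals Σ s·w over products exactly
when the equation is chemically transcribed right. With all weights 1
the same formula degenerates to the mass flux |v|·s, for which
conservation cannot hold in reactions whose summed substrate and
product stoichiometries differ — mass-flux maps are validated per
metabolite, not per reaction.

Direction is data-driven: a negative *v* reverses all edges incident to
the reaction *in the slice's working copy only*. The base network is
immutable, because different conditions may legitimately disagree on
direction (a cycle running forward aerobically and backward
anaerobically). Reactions with *v* = 0 or without a measurement put all
their edges into the zero set: they are kept (rendered dashed) so that
sparse data never hides topology, and slices always have exactly the
base network's edge set.

## Balance validation

*Reaction balance*: inflow = Σ f over incoming edges, outflow over
outgoing; the reaction is balanced when

    |inflow − outflow| ≤ τ · max(inflow, outflow, 1)

with relative tolerance τ = 1e-6 by default (CLI-overridable). Flux
tables are finite-precision decimals, so exact equality would be
meaningless; the max(·,·,1) floor keeps the test sane at zero flux.
Zero-flux reactions would trivially pass 0 = 0, which could hide a
typo, so they get a *structural* check instead — Σ s·w per side,
independent of *v* — reported as a warning, never a failure.

*Metabolite balance*: steady-state production = consumption per label,
summed over all clone nodes of that label (so hub splitting can never
change a verdict). Boundary metabolites (uptake, excretion, biomass
sinks) are exempted only via an explicit external list; nothing is
auto-exempted, because silent exemption creates false passes and silent
inclusion creates false failures. Validation never raises on
unbalanced data — it reports, sorted by descending |residual| with
lexicographic tie-breaks, and the CLI maps "anything failed" to exit
status 3.

## Interaction operators

`split_label` replaces a hub metabolite (ATP, CO₂, ...) by one clone
per incident reaction, clone indices assigned in ascending reaction-
label order; a metabolite appearing as both reactant and product of the
same reaction keeps a single clone carrying both edges. The edge
multiset is untouched, so all flux and balance quantities are invariant
by construction. `unsplit_label` is its exact inverse.
`reconnect_label` builds a purely visual connector overlay (green node
plus one edge per clone) that carries no flux, is excluded from
validation, and is omitted from exports unless requested.

Layout: hierarchical coordinates come from graphviz `dot` when it is on
PATH; otherwise a built-in layered layout runs — longest-path layering
(cycles broken along a deterministic DFS), four barycenter ordering
sweeps with stable tie-breaks, fixed 80 pt within-layer and 90 pt
between-layer spacing. It is fully deterministic and needs no external
binary. Coordinates use the screen convention (origin top-left, y
growing downward, units in points), which matches SVG emission with no
flipping step.

## Rendering

Thickness is linear: max(min_thickness, multiplicator · f); the
multiplicator wording implies linear scaling, and log scaling is
deliberately out of scope. Quality maps to a linear black→red RGB ramp
(red = poor quality: wide confidence interval or high FVA range), with
round-half-up channel rounding so the midpoint is exactly (128, 0, 0);
an `invert_quality` flag covers datasets where larger means better.
Edges inherit their owning reaction's color, so quality stays visible
even with invisible reaction nodes. SVG lengths are emitted with three
decimals and no timestamps, making re-exports byte-identical; PNG is a
Pillow rasterisation at dpi/72 scale of the same geometry.

## Synthetic data

The generator emulates the two dataset shapes the tool targets:
carbon-weighted isotope-tracing experiments (integer weights 1–12,
confidence qualities, two-condition contrasts routing flux to
starch vs lipid sinks with a 70/30 vs 30/70 branch split) and mass-flux
constraint-based datasets (all weights 1, FVA-style variability
qualities including exact zeros, three oxygen conditions, and a
three-reaction cycle that reverses sign between conditions).

Balanced fixtures are balanced *by construction*, not by rejection
sampling: stoichiometries are derived from the weights (s = w_src/w_dst
for a conversion; split fractions f and 1−f for a branch), and fluxes
are propagated through the topology so every internal metabolite is at
steady state; cycles use the telescoping flux recurrence, which closes
exactly. Residuals on clean fixtures are therefore at machine
precision, far below the validation tolerance — no tolerance tuning is
involved in any test.

Corrupted fixtures inject exactly one error of the classic template
classes (misspelled label, glued stoichiometry `2Suc`, doubled
coefficient, dropped reactant) into one reaction and record the ground
truth. The misspelling and gluing injectors also add a weight entry for
the bogus label — a different weight for the misspelling, the original
label's weight for the glued form — since an absent weight would abort
at parse time, and the point of these fixtures is to exercise the
balance validator. Dropping a reactant needs a side with ≥ 2 terms, so
it is only applicable to branched topologies; randomized suites draw
corruption kinds from the applicable set.

Problem sizes used by the test suite and the acceptance script: 200
fixture seeds across chain/branched/cycle topologies with 3–30
reactions for the clean/corrupted validation sweep, 60 mass-flux
fixtures for the unbalance theorem, 30 fixtures (every hub) for
split/unsplit conservation, and 15 for direction adaptation — small
enough to run in seconds while covering every topology × corruption
combination many times over.

What the fixtures do *not* emulate: measurement noise around the
steady state (real ¹³C fits carry residual lack-of-fit), compartment
semantics, cofactor pools entangled across many reactions, and network
scale (hundreds of reactions). Passing tests therefore demonstrate the
correctness of the mapping/validation/rendering machinery, not the
biological plausibility of any particular dataset.

## Design choices and limitations

* The equation grammar requires whitespace between a stoichiometry and
  its label; `2Suc` is a *label*. This keeps the grammar unambiguous
  and is what makes the glued-stoichiometry typo class detectable at
  validation rather than silently misparsed.
* Weight 0 is permitted (a metabolite carrying none of the traced
  element, e.g. ATP in a nitrogen-flux map) and warned about; its edges
  carry zero substance flux.
* Template reactions are matched to network reactions by label,
  case-sensitively; a label match with different reactant/product sets
  is a hard `TopologyConflict`. Set-based matching would be a possible
  extension.
* Formats without node kinds (SIF, plain GML) are classified by the
  documented SIF interaction codes or by two-coloring anchored on known
  reaction labels; an unclassifiable graph is an error, never a guess,
  because silent misclassification corrupts balance validation.
* Missing stoichiometries in GML/SIF default to 1 with a logged
  warning, mirroring the equation parser's default.
* SBML reversibility flags are recorded as node attributes but ignored
  by mapping — direction comes from the flux sign.
* No flux estimation, no fuzzy name suggestions, no unit conversion,
  no charts-on-edges, no GUI: condition/timepoint selection is
  `list_slices` plus an argument, not a slider.
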