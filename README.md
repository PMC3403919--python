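# fluxmap

Visualization and validation of metabolic flux distributions on
bipartite metabolite–reaction networks.

Quantified fluxes — whether measured by isotope tracing (e.g. ¹³C
labeling) or predicted by constraint-based modelling (FBA/FVA) — only
become interpretable when drawn onto the metabolic network they flow
through. `fluxmap` is a library plus CLI for scientists who have a table
of per-reaction flux values and want (a) hard guarantees that the table
is internally consistent and (b) a faithful picture of it.

## The model

A metabolic network is a directed bipartite graph: metabolite nodes and
reaction nodes, with reactant edges *metabolite → reaction* and product
edges *reaction → metabolite*, each carrying the stoichiometric
coefficient *s*. Given a reaction's measured flux *v* (sign = net
direction) and each metabolite's substance weight *w* (traced atoms per
molecule, e.g. carbons; all 1 for mass fluxes), every incident edge
carries the per-edge substance flux

    f = |v| · s · w

drawn with thickness proportional to *f*. A negative *v* reverses the
reaction's edges in that slice of the data; *v* = 0 (or no measurement)
keeps the edges as dashed lines so sparse data never hides topology.

Because *f* counts atoms per time, a correctly transcribed reaction
must satisfy Σf(in) = Σf(out) at its node — atom conservation. An
unbalanced reaction almost always pinpoints a template defect:
a misspelled substance (`Sucr` for `Suc`), a stoichiometry glued to its
label (`2Suc` for `2 Suc`), a wrong coefficient or a dropped reactant.
Metabolite-level balance (production = consumption at steady state,
summed over clones, with explicit boundary exemptions) complements it.
Per-measurement quality values (confidence-interval widths, FVA ranges)
are rendered as a black→red graduation — red meaning *poor*.

## Worked example

```python
from fluxmap import (map_slice, validate_slice, summarize_report,
                     layout_dot, style_slice, StyleOptions, export_svg)
from fluxmap.fixtures import usecase_seed_toy

toy = usecase_seed_toy(seed=3)           # 2 conditions, carbon weights
for cond in ("A", "B"):
    slc = map_slice(toy.network, toy.experiment, cond, "t0")
    report = validate_slice(slc, external_labels=toy.external_labels)
    status, text, _ = summarize_report(report)
    print(text)
    starch = slc.network.nodes_for_label("starch")[0]
    influx = sum(slc.flux_of(e)
                 for e in slc.network.graph.in_edges(starch))
    print(f"  flux into starch under {cond}: {influx:g}")
    styled = style_slice(slc, layout_dot(slc.network),
                         StyleOptions(quality_mode="red_graduation"))
    export_svg(styled, f"map_{cond}.svg")
```

prints

```
slice condition='A' timepoint='t0' (tolerance 1e-06)
all reactions and metabolites balanced
  flux into starch under A: 84
slice condition='B' timepoint='t0' (tolerance 1e-06)
all reactions and metabolites balanced
  flux into starch under B: 36
```

Both slices validate cleanly (status 0), and the starch influx — 14
molecules/time × 6 carbons under condition A versus 6 × 6 under B —
shows the designed 70/30 vs 30/70 storage switch; the two SVGs show it
as edge thickness.

The same workflow from the shell:

```sh
fluxmap fixtures --spec branched --n 6 --seed 42 --out demo/
fluxmap validate --data demo/template.csv --network demo/network.gml
fluxmap render --data demo/template.csv --condition C1 --timepoint T1 \
    --multiplicator 2 --quality red --out demo/map.svg
```

`fluxmap validate` exits with status 0 when everything balances and 3
otherwise, so it can gate a pipeline.

## File formats

* **Flux template** (CSV or single-sheet xlsx): sections `#METADATA`,
  `#CONDITIONS`, `#TIMEPOINTS`, `#WEIGHTS`, `#REACTIONS` (name,
  equation), `#FLUXES` (reaction, condition, timepoint, value, optional
  quality). Equations use `->`/`=>`/`→`/`-->` with `+`-separated terms;
  a stoichiometry must be whitespace-separated from its label.
* **Networks**: SBML (Level 2/3 core), GML and SIF in; GML and GraphML
  out (round-trip lossless, visual attributes included). The SIF
  dialect is one edge per line, `SOURCE<TAB>rp<TAB>REACTION` for
  reactant edges and `REACTION<TAB>pr<TAB>PRODUCT` for product edges.
* **Images**: deterministic standalone SVG; PNG at any dpi.

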