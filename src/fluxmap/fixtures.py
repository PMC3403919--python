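"""Deterministic synthetic networks and flux templates for every module.

The generator produces small metabolic topologies (chains, branched
trees, cycles and a hand-built central-metabolism toy) together with
flux experiments that are *balanced by construction*: stoichiometries
are chosen so that every reaction conserves weighted atoms exactly
(``sum s*w`` equal on both sides), and fluxes are propagated through the
topology so that every internal metabolite is at steady state.  Balance
therefore never depends on tolerance luck, and a validator failure on a
clean fixture is always a real defect.

Corrupted fixtures start from a balanced one and inject exactly one of
the classic template error classes — a misspelled substance name
(``Sucr`` for ``Suc``), a stoichiometry glued to its label (``2Suc`` for
``2 Suc``), a wrong stoichiometric factor, or a dropped reactant — and
record the ground-truth location, so validator output can be checked for
exact agreement.  The spelled-out error classes would normally also
break weight lookup at parse time; the injector adds a weight entry for
the bogus label (a different weight for the misspelling, the original
weight for the glued form) precisely so the defect survives parsing and
surfaces where it is hardest to see: at balance validation.

Two ready-made use-case fixtures emulate the common shapes of flux
datasets: a carbon-weighted isotope-tracing experiment with two
conditions, confidence qualities and starch/lipid sink metabolites, and
a mass-flux (all weights 1) constraint-based-modelling dataset with
three oxygen conditions, flux-variability qualities and a cycle whose
direction reverses between conditions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .dataset_io import (
    FluxExperiment,
    Measurement,
    ReactionEquation,
    _format_number,
)
from .errors import SpecError
from .network_model import MetabolicNetwork, network_from_experiment

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "UseCaseFixture",
    "generate",
    "applicable_corruptions",
    "usecase_seed_toy",
    "usecase_fba_toy",
    "TOPOLOGIES",
    "CORRUPTIONS",
]

TOPOLOGIES = ("chain", "branched", "cycle", "central_metabolism_toy")
WEIGHTS_MODES = ("carbon_like", "mass")
QUALITY_MODES = ("none", "confidence", "variability")
CORRUPTIONS = ("misspell_label", "glued_stoichiometry",
               "wrong_stoichiometry", "missing_reactant")


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a generated fixture (seed included)."""

    topology: str = "chain"
    n_reactions: int = 3
    weights_mode: str = "carbon_like"
    n_conditions: int = 1
    n_timepoints: int = 1
    quality_mode: str = "none"
    seed: int = 0
    corruption: str | None = None
    corruption_target: str | None = None

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise SpecError(f"unknown topology {self.topology!r}")
        if self.weights_mode not in WEIGHTS_MODES:
            raise SpecError(f"unknown weights_mode {self.weights_mode!r}")
        if self.quality_mode not in QUALITY_MODES:
            raise SpecError(f"unknown quality_mode {self.quality_mode!r}")
        if self.corruption is not None and self.corruption not in CORRUPTIONS:
            raise SpecError(f"unknown corruption {self.corruption!r}")
        if self.n_reactions < 1 or self.n_conditions < 1 \
                or self.n_timepoints < 1:
            raise SpecError("sizes must be positive")
        if self.topology == "cycle" and self.n_reactions < 3:
            raise SpecError("a cycle needs at least 3 reactions")
        if self.topology == "branched" and self.n_reactions < 3:
            raise SpecError("a branched topology needs at least 3 reactions")


@dataclass
class FixtureBundle:
    """Generated network + experiment, plus ground truth for corruption."""

    network: MetabolicNetwork
    experiment: FluxExperiment
    external_labels: set[str] = field(default_factory=set)
    corruption: tuple[str, str] | None = None  # (kind, reaction name)

    def __iter__(self):
        return iter((self.network, self.experiment))


@dataclass
class UseCaseFixture(FixtureBundle):
    """A use-case bundle with the designed contrasts spelled out."""

    sink_labels: tuple[str, ...] = ()
    branch_fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Topology construction (balanced by design)
# ---------------------------------------------------------------------------

def _met(i: int) -> str:
    return f"Met{i:02d}"


def _rxn(i: int) -> str:
    return f"r{i:02d}"


def _draw_weights(rng: random.Random, n: int, mode: str) -> list[int]:
    if mode == "mass":
        return [1] * n
    weights = [rng.randint(1, 12)]
    for _ in range(n - 1):
        w = rng.randint(1, 12)
        while w == weights[-1]:  # adjacent-distinct => non-unit stoich exist
            w = rng.randint(1, 12)
        weights.append(w)
    return weights


def _mass_stoich(rng: random.Random) -> float:
    return rng.choice([1.0, 2.0, 0.5])


def _build_chain(rng: random.Random, spec: FixtureSpec):
    n = spec.n_reactions
    weights = {_met(i): w
               for i, w in enumerate(_draw_weights(rng, n + 1,
                                                   spec.weights_mode))}
    reactions: list[ReactionEquation] = []
    base_flux: dict[str, float] = {}
    v = round(rng.uniform(1.0, 10.0), 3)
    forced_mass = rng.randrange(n)  # guarantee one unequal-count reaction
    for i in range(1, n + 1):
        src, dst = _met(i - 1), _met(i)
        if spec.weights_mode == "mass":
            s = 2.0 if i - 1 == forced_mass else _mass_stoich(rng)
        else:
            s = weights[src] / weights[dst]
        reactions.append(ReactionEquation(
            name=_rxn(i), reactants=((src, 1.0),), products=((dst, s),)))
        base_flux[_rxn(i)] = v
        v = v * s if spec.weights_mode == "mass" \
            else v * weights[src] / weights[dst]
    external = {_met(0), _met(n)}
    return weights, reactions, base_flux, external


def _build_cycle(rng: random.Random, spec: FixtureSpec):
    n = spec.n_reactions
    weights = {_met(i): w
               for i, w in enumerate(_draw_weights(rng, n,
                                                   spec.weights_mode))}
    if spec.weights_mode == "mass":
        # the stoichiometry product around the cycle must be 1 for a
        # steady state; 2 * 0.5 * 1 * ... gives unequal-count reactions
        s_list = [2.0, 0.5] + [1.0] * (n - 2)
    else:
        s_list = [weights[_met(i - 1)] / weights[_met(i % n)]
                  for i in range(1, n + 1)]
    reactions: list[ReactionEquation] = []
    base_flux: dict[str, float] = {}
    v = round(rng.uniform(1.0, 10.0), 3)
    for i in range(1, n + 1):
        src, dst = _met(i - 1), _met(i % n)
        s = s_list[i - 1]
        reactions.append(ReactionEquation(
            name=_rxn(i), reactants=((src, 1.0),), products=((dst, s),)))
        base_flux[_rxn(i)] = v
        v = v * s if spec.weights_mode == "mass" \
            else v * weights[src] / weights[dst]
    return weights, reactions, base_flux, set()


def _build_branched(rng: random.Random, spec: FixtureSpec):
    """A stem chain, a 1->2 split reaction, then two branch chains.

    Reaction budget: ``n_stem`` stem steps + 1 split + the rest split
    between the two branches.  Metabolite labels: the stem needs
    n_stem+1, each branch needs (its reactions)+1, totalling n+2.
    """
    n = spec.n_reactions
    n_stem = max(1, (n - 1) // 3)
    n_rest = n - n_stem - 1
    n_left = n_rest // 2
    n_right = n_rest - n_left

    mode = spec.weights_mode
    labels = [_met(i) for i in range(n + 2)]
    weights = dict(zip(labels, _draw_weights(rng, len(labels), mode)))
    stem = labels[:n_stem + 1]
    left = labels[n_stem + 1:n_stem + 2 + n_left]
    right = labels[n_stem + 2 + n_left:]
    assert len(right) == n_right + 1
    hub = stem[-1]

    reactions: list[ReactionEquation] = []
    base_flux: dict[str, float] = {}
    ridx = 0

    def chain_step(src: str, dst: str, v: float) -> float:
        nonlocal ridx
        ridx += 1
        s = _mass_stoich(rng) if mode == "mass" \
            else weights[src] / weights[dst]
        reactions.append(ReactionEquation(
            name=_rxn(ridx), reactants=((src, 1.0),), products=((dst, s),)))
        base_flux[_rxn(ridx)] = v
        return v * s

    v = round(rng.uniform(1.0, 10.0), 3)
    for i in range(n_stem):
        v = chain_step(stem[i], stem[i + 1], v)

    # split: fraction f of the hub's atoms go left, the rest right
    f = round(rng.uniform(0.25, 0.75), 3)
    ridx += 1
    if mode == "mass":
        sl, sr = 2.0, 1.0  # 1 molecule -> 3: unequal counts guaranteed
    else:
        sl = f * weights[hub] / weights[left[0]]
        sr = (1 - f) * weights[hub] / weights[right[0]]
    reactions.append(ReactionEquation(
        name=_rxn(ridx), reactants=((hub, 1.0),),
        products=((left[0], sl), (right[0], sr))))
    base_flux[_rxn(ridx)] = v

    vv = v * sl
    for k in range(n_left):
        vv = chain_step(left[k], left[k + 1], vv)
    vv = v * sr
    for k in range(n_right):
        vv = chain_step(right[k], right[k + 1], vv)

    external = {stem[0], left[-1], right[-1]}
    return weights, reactions, base_flux, external


def _build_central_toy(rng: random.Random, spec: FixtureSpec):
    return _central_metabolism(rng, starch_fraction=0.5)


def _central_metabolism(rng: random.Random, starch_fraction: float):
    """Sucrose -> hexose -> {starch | triose -> lipids} with carbon weights."""
    weights = {"Suc": 12, "Hex": 6, "TP": 3, "starch": 6, "lipids": 6}
    reactions = [
        ReactionEquation("inv", (("Suc", 1.0),), (("Hex", 2.0),)),
        ReactionEquation("starch_syn", (("Hex", 1.0),), (("starch", 1.0),)),
        ReactionEquation("glyc", (("Hex", 1.0),), (("TP", 2.0),)),
        ReactionEquation("lipid_syn", (("TP", 2.0),), (("lipids", 1.0),)),
    ]
    v_inv = 10.0
    hex_prod = 2 * v_inv
    v_starch = starch_fraction * hex_prod
    v_glyc = (1 - starch_fraction) * hex_prod
    v_lipid = v_glyc * 2 / 2  # 2 TP per glyc, 2 TP per lipid unit
    base_flux = {"inv": v_inv, "starch_syn": v_starch,
                 "glyc": v_glyc, "lipid_syn": v_lipid}
    external = {"Suc", "starch", "lipids"}
    return weights, reactions, base_flux, external


_BUILDERS = {
    "chain": _build_chain,
    "branched": _build_branched,
    "cycle": _build_cycle,
    "central_metabolism_toy": _build_central_toy,
}


# ---------------------------------------------------------------------------
# Quality values and measurement assembly
# ---------------------------------------------------------------------------

def _quality(rng: random.Random, mode: str) -> float | None:
    if mode == "none":
        return None
    if mode == "confidence":
        return round(rng.uniform(0.01, 0.3), 4)
    # variability: nonnegative, occasionally exactly zero
    return 0.0 if rng.random() < 0.25 else round(rng.uniform(0.1, 5.0), 3)


def _assemble_experiment(rng: random.Random, spec: FixtureSpec, weights,
                         reactions, base_flux) -> FluxExperiment:
    conditions = [f"C{j + 1}" for j in range(spec.n_conditions)]
    timepoints = [f"T{k + 1}" for k in range(spec.n_timepoints)]
    measurements = []
    for cond in conditions:
        for tp in timepoints:
            scale = round(rng.uniform(0.5, 2.0), 3)
            for rxn in reactions:
                measurements.append(Measurement(
                    reaction_name=rxn.name, condition=cond, timepoint=tp,
                    flux_value=base_flux[rxn.name] * scale,
                    quality=_quality(rng, spec.quality_mode)))
    return FluxExperiment(
        metadata={"generator": "fluxmap.fixtures",
                  "topology": spec.topology,
                  "seed": str(spec.seed)},
        conditions=conditions, timepoints=timepoints,
        substance_weights=dict(weights), reactions=list(reactions),
        measurements=measurements)


# ---------------------------------------------------------------------------
# Corruption injection
# ---------------------------------------------------------------------------

def _fresh_label(base: str, weights: dict) -> str:
    label = base
    while label in weights:
        label += "r"
    return label


def applicable_corruptions(experiment: FluxExperiment) -> list[str]:
    """Corruption kinds that have at least one viable target reaction."""
    kinds = ["misspell_label", "wrong_stoichiometry"]
    if any(s != 1.0 for r in experiment.reactions
           for _, s in (*r.reactants, *r.products)):
        kinds.insert(1, "glued_stoichiometry")
    if any(len(r.reactants) > 1 or len(r.products) > 1
           for r in experiment.reactions):
        kinds.append("missing_reactant")
    return kinds


def _inject(rng: random.Random, experiment: FluxExperiment, kind: str,
            target: str | None) -> tuple[str, str]:
    """Mutate one reaction in place; returns (kind, reaction name)."""
    def targets():
        if kind == "glued_stoichiometry":
            return [r for r in experiment.reactions
                    if any(s != 1.0 for _, s in (*r.reactants, *r.products))]
        if kind == "missing_reactant":
            return [r for r in experiment.reactions
                    if len(r.reactants) > 1 or len(r.products) > 1]
        return list(experiment.reactions)

    candidates = targets()
    if target is not None:
        candidates = [r for r in candidates if r.name == target]
    if not candidates:
        raise SpecError(
            f"no reaction admits corruption {kind!r}"
            + (f" with target {target!r}" if target else ""))
    rxn = candidates[rng.randrange(len(candidates))]
    idx = experiment.reactions.index(rxn)
    reactants, products = list(rxn.reactants), list(rxn.products)
    w = experiment.substance_weights

    if kind == "misspell_label":
        side = reactants if reactants else products
        i = rng.randrange(len(side))
        lab, s = side[i]
        bad = _fresh_label(lab + "r", w)
        w[bad] = w[lab] + 1  # a different weight => nonzero residual
        side[i] = (bad, s)
    elif kind == "glued_stoichiometry":
        terms = [(True, i) for i, (_, s) in enumerate(reactants) if s != 1.0]
        terms += [(False, i) for i, (_, s) in enumerate(products) if s != 1.0]
        is_reactant, i = terms[rng.randrange(len(terms))]
        side = reactants if is_reactant else products
        lab, s = side[i]
        glued = _fresh_label(f"{_format_number(s)}{lab}", w)
        w[glued] = w[lab]  # the typo'd name inherits the real weight
        side[i] = (glued, 1.0)
    elif kind == "wrong_stoichiometry":
        all_terms = [(True, i) for i in range(len(reactants))]
        all_terms += [(False, i) for i in range(len(products))]
        is_reactant, i = all_terms[rng.randrange(len(all_terms))]
        side = reactants if is_reactant else products
        lab, s = side[i]
        side[i] = (lab, s * 2.0)
    elif kind == "missing_reactant":
        if len(reactants) > 1:
            reactants.pop(rng.randrange(len(reactants)))
        else:
            products.pop(rng.randrange(len(products)))
    else:  # pragma: no cover
        raise SpecError(f"unknown corruption {kind!r}")

    experiment.reactions[idx] = ReactionEquation(
        rxn.name, tuple(reactants), tuple(products))
    return kind, rxn.name


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a (network, experiment) bundle; the seed fixes everything."""
    rng = random.Random(spec.seed)
    weights, reactions, base_flux, external = _BUILDERS[spec.topology](
        rng, spec)
    experiment = _assemble_experiment(rng, spec, weights, reactions,
                                      base_flux)
    corruption = None
    if spec.corruption is not None:
        corruption = _inject(rng, experiment, spec.corruption,
                             spec.corruption_target)
    experiment.validate()
    network = network_from_experiment(experiment)
    return FixtureBundle(network=network, experiment=experiment,
                         external_labels=set(external),
                         corruption=corruption)


def usecase_seed_toy(seed: int = 0,
                     split_a: float = 0.7,
                     split_b: float = 0.3) -> UseCaseFixture:
    """Carbon-flux toy: two conditions routing sugar to starch vs lipids.

    Condition ``A`` routes ``split_a`` of the hexose flux to starch (and
    the rest toward lipids); condition ``B`` uses ``split_b``.  Weights
    are carbon counts, qualities are confidence values, and the sink
    metabolites ``starch``/``lipids`` carry a yellow fill attribute.
    """
    rng = random.Random(seed)
    experiments = []
    for frac in (split_a, split_b):
        weights, reactions, base_flux, external = _central_metabolism(
            rng, starch_fraction=frac)
        experiments.append((weights, reactions, base_flux, external))
    weights, reactions, _, external = experiments[0]

    measurements = []
    for cond, (_, _, base_flux, _) in zip("AB", experiments):
        for rxn in reactions:
            measurements.append(Measurement(
                reaction_name=rxn.name, condition=cond, timepoint="t0",
                flux_value=base_flux[rxn.name],
                quality=round(rng.uniform(0.01, 0.2), 4)))
    experiment = FluxExperiment(
        metadata={"experiment": "seed carbon flux toy", "seed": str(seed)},
        conditions=["A", "B"], timepoints=["t0"],
        substance_weights=weights, reactions=reactions,
        measurements=measurements)
    experiment.validate()
    network = network_from_experiment(experiment)
    for sink in ("starch", "lipids"):
        node = network.nodes_for_label(sink)[0]
        network.graph.nodes[node]["fill"] = "#ffff00"
    return UseCaseFixture(
        network=network, experiment=experiment,
        external_labels=set(external),
        sink_labels=("starch", "lipids"),
        branch_fractions={"A": split_a, "B": split_b})


def usecase_fba_toy(seed: int = 0) -> UseCaseFixture:
    """Mass-flux toy: three oxygen conditions, FVA-style qualities.

    All weights are 1.  A three-reaction cycle (OAA -> Cit -> Mal -> OAA)
    runs forward under ``aerobic``, backward under ``anoxic`` (negative
    fluxes: direction adaptation) and is shut off under ``hypoxic``
    (dashed zero-flux edges).  The uptake reaction has quality 0 — no
    flux variability, drawn black.  Uptake/excretion metabolites are the
    designated externals; internal metabolites are mass-balanced in every
    condition.
    """
    rng = random.Random(seed)
    weights = {m: 1 for m in ("Glc_ext", "Glc", "Pyr", "EtOH", "CO2",
                              "OAA", "Cit", "Mal")}
    reactions = [
        ReactionEquation("upt", (("Glc_ext", 1.0),), (("Glc", 1.0),)),
        ReactionEquation("gly", (("Glc", 1.0),), (("Pyr", 2.0),)),
        ReactionEquation("ferm", (("Pyr", 1.0),), (("EtOH", 1.0),)),
        ReactionEquation("resp", (("Pyr", 1.0),), (("CO2", 1.0),)),
        ReactionEquation("tca1", (("OAA", 1.0),), (("Cit", 1.0),)),
        ReactionEquation("tca2", (("Cit", 1.0),), (("Mal", 1.0),)),
        ReactionEquation("tca3", (("Mal", 1.0),), (("OAA", 1.0),)),
    ]
    flux_by_condition = {
        "anoxic": {"upt": 10.0, "gly": 10.0, "ferm": 20.0, "resp": 0.0,
                   "tca1": -5.0, "tca2": -5.0, "tca3": -5.0},
        "hypoxic": {"upt": 10.0, "gly": 10.0, "ferm": 10.0, "resp": 10.0,
                    "tca1": 0.0, "tca2": 0.0, "tca3": 0.0},
        "aerobic": {"upt": 10.0, "gly": 10.0, "ferm": 0.0, "resp": 20.0,
                    "tca1": 5.0, "tca2": 5.0, "tca3": 5.0},
    }
    measurements = []
    for cond, fluxes in flux_by_condition.items():
        for rxn in reactions:
            q = 0.0 if rxn.name == "upt" else _quality(rng, "variability")
            measurements.append(Measurement(
                reaction_name=rxn.name, condition=cond, timepoint="t0",
                flux_value=fluxes[rxn.name], quality=q))
    experiment = FluxExperiment(
        metadata={"experiment": "oxygen mass flux toy", "seed": str(seed)},
        conditions=["anoxic", "hypoxic", "aerobic"], timepoints=["t0"],
        substance_weights=weights, reactions=reactions,
        measurements=measurements)
    experiment.validate()
    network = network_from_experiment(experiment)
    return UseCaseFixture(
        network=network, experiment=experiment,
        external_labels={"Glc_ext", "EtOH", "CO2"},
        sink_labels=("EtOH", "CO2"))
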