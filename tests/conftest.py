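import pytest

from fluxmap.dataset_io import (
    FluxExperiment,
    Measurement,
    parse_reaction_equation,
)
from fluxmap.network_model import network_from_experiment
from fluxmap import fixtures as fx


def make_experiment(equations, weights, fluxes, conditions=("C1",),
                    timepoints=("T1",), qualities=None):
    """Hand-rolled experiment builder for small explicit test cases.

    ``fluxes`` maps reaction name -> value (applied to every slice) or
    (name, condition, timepoint) -> value.
    """
    reactions = [parse_reaction_equation(eq, name) for name, eq in equations]
    measurements = []
    for c in conditions:
        for t in timepoints:
            for name, _ in equations:
                if (name, c, t) in fluxes:
                    v = fluxes[(name, c, t)]
                elif name in fluxes:
                    v = fluxes[name]
                else:
                    continue
                q = (qualities or {}).get(name)
                measurements.append(Measurement(name, c, t, v, q))
    exp = FluxExperiment(
        metadata={"source": "unit test"},
        conditions=list(conditions), timepoints=list(timepoints),
        substance_weights=dict(weights), reactions=reactions,
        measurements=measurements)
    exp.validate()
    return exp


@pytest.fixture
def sucrose_experiment():
    """Sucrose cleavage: 12 carbons in, 6+6 out, balanced at v=1."""
    return make_experiment(
        equations=[("inv", "Suc -> Fru + Glc")],
        weights={"Suc": 12, "Fru": 6, "Glc": 6},
        fluxes={"inv": 1.0})


@pytest.fixture
def chain_experiment():
    """A -> B -> C, unit weights and stoichiometries, flux 1 each."""
    return make_experiment(
        equations=[("r1", "A -> B"), ("r2", "B -> C")],
        weights={"A": 1, "B": 1, "C": 1},
        fluxes={"r1": 1.0, "r2": 1.0})


@pytest.fixture
def hub_experiment():
    """ATP_c shared by several reactions: the splitting test bed."""
    return make_experiment(
        equations=[
            ("hk", "Glc + ATP_c -> G6P + ADP_c"),
            ("pfk", "F6P + ATP_c -> FBP + ADP_c"),
            ("pk", "PEP + ADP_c -> Pyr + ATP_c"),
            ("iso", "G6P -> F6P"),
        ],
        weights={"Glc": 6, "G6P": 6, "F6P": 6, "FBP": 6, "PEP": 3,
                 "Pyr": 3, "ATP_c": 10, "ADP_c": 10},
        fluxes={"hk": 1.0, "pfk": 1.0, "pk": 2.0, "iso": 1.0})


@pytest.fixture
def hub_network(hub_experiment):
    return network_from_experiment(hub_experiment)


@pytest.fixture
def seed_toy():
    return fx.usecase_seed_toy(seed=42)


@pytest.fixture
def fba_toy():
    return fx.usecase_fba_toy(seed=42)


def two_coloring_oracle(network):
    """Independent bipartiteness check: BFS 2-coloring on the undirected
    edge list, without networkx's bipartite helpers."""
    adj = {}
    for u, v in network.graph.edges():
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    color = {}
    for start in network.graph.nodes():
        if start in color:
            continue
        color[start] = 0
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in adj.get(node, ()):
                if nb not in color:
                    color[nb] = 1 - color[node]
                    queue.append(nb)
                elif color[nb] == color[node]:
                    return False
    return True
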