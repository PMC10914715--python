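import itertools

import numpy as np
import pytest

from metsnet.fixtures import build_published_fixture
from metsnet.network import CategoricalVariable, Cpt, Dag, DiscreteBayesNet


@pytest.fixture(scope="session")
def progression_net():
    return build_published_fixture("progression")


@pytest.fixture(scope="session")
def recovery_net():
    return build_published_fixture("recovery")


def make_random_net(
    rng: np.random.Generator,
    n_nodes: int | None = None,
    max_nodes: int = 10,
    max_states: int = 4096,
) -> DiscreteBayesNet:
    """Random DAG + random Dirichlet CPTs, state space capped for enumeration."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, max_nodes + 1))
    names = [f"x{i}" for i in range(n_nodes)]
    cards, total = [], 1
    for _ in names:
        c = 3 if (rng.random() < 0.3 and total * 3 <= max_states) else 2
        if total * c > max_states:
            c = 2
        cards.append(c)
        total *= c
    variables = [
        CategoricalVariable(nm, tuple(f"l{j}" for j in range(c)))
        for nm, c in zip(names, cards)
    ]
    order = rng.permutation(n_nodes)
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < 0.4:
            u, v = order[i], order[j]
            edges.append((names[u], names[v]))
    dag = Dag(names, edges)
    cpts = {}
    for var in variables:
        parents = dag.parents(var.name)
        rows = {}
        for combo in itertools.product(
            *({v.name: v for v in variables}[p].levels for p in parents)
        ):
            rows[combo] = rng.dirichlet(np.ones(var.cardinality))
        cpts[var.name] = Cpt(var.name, parents, rows)
    return DiscreteBayesNet(variables=variables, dag=dag, cpts=cpts)
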