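import numpy as np
import pytest

from cscc_bn.inference import Evidence
from cscc_bn.network import (
    BayesianNetworkModel,
    CPT,
    CPTRule,
    EdgeSpec,
    NodeSpec,
    compile_cpt,
)
from cscc_bn.reference import build_reference_model


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_model()


def make_chain_model(p_a1=0.6, p_b1_given_a1=0.7, p_b1_given_a2=0.3):
    """Two-node chain A -> B with binary states."""
    a = NodeSpec("A", ("a1", "a2"))
    b = NodeSpec("B", ("b1", "b2"))
    rules = [
        CPTRule.make("A", {}, {"a1": p_a1, "a2": 1 - p_a1}),
        CPTRule.make("B", {"A": "a1"}, {"b1": p_b1_given_a1, "b2": 1 - p_b1_given_a1}),
        CPTRule.make("B", {"A": "a2"}, {"b1": p_b1_given_a2, "b2": 1 - p_b1_given_a2}),
    ]
    model = BayesianNetworkModel(nodes=[a, b], edges=[EdgeSpec("A", "B")], cpt_rules=rules)
    model.cpts["A"] = compile_cpt([rules[0]], a, [])
    model.cpts["B"] = compile_cpt(rules[1:], b, [a])
    return model


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def laryngeal_model():
    """Naive-Bayes screening fixture: malignancy T with two conditionally
    independent findings, hoarseness H and an imaging lesion I."""
    t = NodeSpec("T", ("present", "absent"))
    h = NodeSpec("H", ("true", "false"))
    i = NodeSpec("I", ("true", "false"))
    rules = [
        CPTRule.make("T", {}, {"present": 0.1, "absent": 0.9}),
        CPTRule.make("H", {"T": "present"}, {"true": 0.8, "false": 0.2}),
        CPTRule.make("H", {"T": "absent"}, {"true": 0.2, "false": 0.8}),
        CPTRule.make("I", {"T": "present"}, {"true": 0.9, "false": 0.1}),
        CPTRule.make("I", {"T": "absent"}, {"true": 0.05, "false": 0.95}),
    ]
    model = BayesianNetworkModel(
        nodes=[t, h, i],
        edges=[EdgeSpec("T", "H"), EdgeSpec("T", "I")],
        cpt_rules=rules,
    )
    model.cpts["T"] = compile_cpt(rules[:1], t, [])
    model.cpts["H"] = compile_cpt(rules[1:3], h, [t])
    model.cpts["I"] = compile_cpt(rules[3:], i, [t])
    return model


def random_model(rng: np.random.Generator, max_nodes: int = 7, max_states: int = 4) -> BayesianNetworkModel:
    """A random small DAG with strictly positive random CPTs."""
    n_nodes = int(rng.integers(2, max_nodes + 1))
    nodes = [
        NodeSpec(f"X{i}", tuple(f"s{k}" for k in range(int(rng.integers(2, max_states + 1)))))
        for i in range(n_nodes)
    ]
    edges = [
        EdgeSpec(nodes[i].name, nodes[j].name)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.35
    ]
    model = BayesianNetworkModel(nodes=nodes, edges=edges)
    for node in nodes:
        parents = [model.node(p) for p in model.parents_of(node.name)]
        n_rows = int(np.prod([p.cardinality for p in parents])) if parents else 1
        raw = rng.random((n_rows, node.cardinality)) + 0.05  # bounded away from 0
        rows = raw / raw.sum(axis=1, keepdims=True)
        model.cpts[node.name] = CPT(node.name, tuple(p.name for p in parents), rows)
    return model


def random_evidence(rng: np.random.Generator, model: BayesianNetworkModel, p_observe: float = 0.3):
    """Random partial evidence plus an unobserved query node."""
    observed = {}
    for node in model.nodes:
        if rng.random() < p_observe:
            observed[node.name] = node.states[int(rng.integers(node.cardinality))]
    free = [n.name for n in model.nodes if n.name not in observed]
    if not free:
        drop = model.nodes[int(rng.integers(len(model.nodes)))].name
        observed.pop(drop)
        free = [drop]
    query = free[int(rng.integers(len(free)))]
    return Evidence.from_map(observed), query
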