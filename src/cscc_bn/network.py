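"""Data model for discrete Bayesian networks.

A network is a directed acyclic graph over categorical nodes, each carrying a
conditional probability table (CPT) ``P(node | parents)``.  The joint
distribution factorizes as ``P(X1,...,Xn) = prod_i P(Xi | Pa(Xi))``.

CPTs are authored as compact *rules*: a rule fixes the states of a subset of
the child's parents (unlisted parents are wildcards) and supplies one
distribution over the child's states.  :func:`compile_cpt` expands a rule set
into a full table, resolving overlaps by most-specific-match; genuinely
ambiguous rule sets are rejected rather than silently prioritized, which keeps
model files auditable.

Row indexing is mixed-radix with the first-listed parent most significant and
states in declared order, so that compiled tables are portable bit-exactly.
Probabilities are stored as decimals in ``[0, 1]``; percentages appear only at
I/O boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "CPTRule",
    "CPT",
    "BayesianNetworkModel",
    "ValidationIssue",
    "ValidationReport",
    "ModelError",
    "AmbiguityError",
    "CoverageError",
    "validate_model",
    "compile_cpt",
    "joint_probability",
]

#: normalization tolerance for CPT rows
ROW_SUM_TOL = 1e-9


class ModelError(ValueError):
    """A structurally invalid model element or query input."""


class AmbiguityError(ModelError):
    """Two equally specific rules with different distributions match one
    parent combination."""


class CoverageError(ModelError):
    """Some parent combination is matched by no rule."""


@dataclass(frozen=True)
class NodeSpec:
    """A categorical variable with an ordered state space.

    ``group`` is a free thematic tag (e.g. ``"tnm"``, ``"pdl1"``,
    ``"treatment"``) used only for display and model organization.
    """

    name: str
    states: tuple[str, ...]
    group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ModelError(
                f"node {self.name!r} has no state {state!r}; "
                f"valid states are {list(self.states)}"
            ) from None


@dataclass(frozen=True)
class EdgeSpec:
    """A directed dependency ``parent -> child``."""

    parent: str
    child: str


@dataclass(frozen=True)
class CPTRule:
    """A compact CPT authoring rule for one child node.

    ``pattern`` maps a subset of the child's parents to required states;
    parents absent from the pattern are wildcards.  ``distribution`` gives one
    probability per child state.  Specificity is the number of non-wildcard
    entries; the most specific matching rule supplies each table row.
    """

    child: str
    pattern: tuple[tuple[str, str], ...]  # sorted (parent, state) pairs
    distribution: tuple[tuple[str, float], ...]  # (state, probability) pairs

    @staticmethod
    def make(child: str, pattern: dict[str, str], distribution: dict[str, float]) -> "CPTRule":
        return CPTRule(
            child=child,
            pattern=tuple(sorted(pattern.items())),
            distribution=tuple(distribution.items()),
        )

    @property
    def specificity(self) -> int:
        return len(self.pattern)

    @property
    def pattern_map(self) -> dict[str, str]:
        return dict(self.pattern)

    @property
    def distribution_map(self) -> dict[str, float]:
        return dict(self.distribution)

    def matches(self, combo: dict[str, str]) -> bool:
        return all(combo.get(p) == s for p, s in self.pattern)


@dataclass
class CPT:
    """A fully expanded conditional probability table for one node.

    ``rows`` has one probability vector over the child's states per full
    parent-state combination; row order is mixed-radix over the parent list
    (first parent most significant).  Root nodes have an empty parent list and
    a single prior row.
    """

    child: str
    parents: tuple[str, ...]
    rows: np.ndarray  # shape (n_combinations, n_child_states)

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise ModelError(f"CPT for {self.child!r}: rows must be 2-D")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CPT):
            return NotImplemented
        return (
            self.child == other.child
            and self.parents == other.parents
            and np.array_equal(self.rows, other.rows)
        )


def row_index(parent_specs: list[NodeSpec], combo: dict[str, str]) -> int:
    """Mixed-radix row index of a full parent-state combination.

    The first-listed parent is the most significant digit; states count in
    their declared order.
    """
    idx = 0
    for spec in parent_specs:
        idx = idx * spec.cardinality + spec.state_index(combo[spec.name])
    return idx


@dataclass
class BayesianNetworkModel:
    """A discrete Bayesian network: nodes, edges, and one CPT per node.

    ``cpt_rules`` retains the compact authored form so that models round-trip
    through the file dialect without loss.
    """

    nodes: list[NodeSpec]
    edges: list[EdgeSpec]
    cpts: dict[str, CPT] = field(default_factory=dict)
    cpt_rules: list[CPTRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {n.name: n for n in self.nodes}

    def node(self, name: str) -> NodeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"unknown node {name!r}") from None

    def has_node(self, name: str) -> bool:
        return name in self._by_name

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def parents_of(self, name: str) -> list[str]:
        return [e.parent for e in self.edges if e.child == name]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BayesianNetworkModel):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.cpts == other.cpts
            and self.cpt_rules == other.cpt_rules
        )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, severity: str, code: str, message: str, location: str) -> None:
        self.issues.append(ValidationIssue(severity, code, message, location))

    def __iter__(self):
        return iter(self.issues)

    def __len__(self) -> int:
        return len(self.issues)


def validate_model(model: BayesianNetworkModel) -> ValidationReport:
    """Check every structural invariant; violations become report entries.

    The report is empty iff the model is valid.  Checks: node-name and
    state-label uniqueness, minimum state count, edge endpoints, self-edges,
    acyclicity, one CPT per node with the graph's parent list, row counts, and
    per-row normalization within ``ROW_SUM_TOL``.
    """
    report = ValidationReport()

    seen: set[str] = set()
    for n in model.nodes:
        if n.name in seen:
            report.add("error", "duplicate_node", f"node name {n.name!r} repeated", n.name)
        seen.add(n.name)
        if len(n.states) < 2:
            report.add("error", "too_few_states", f"node {n.name!r} has {len(n.states)} state(s); need >= 2", n.name)
        if len(set(n.states)) != len(n.states):
            report.add("error", "duplicate_state", f"node {n.name!r} has repeated state labels", n.name)

    for e in model.edges:
        loc = f"{e.parent}->{e.child}"
        if e.parent not in seen or e.child not in seen:
            report.add("error", "edge_endpoint", f"edge {loc} references an unknown node", loc)
        elif e.parent == e.child:
            report.add("error", "self_edge", f"self-edge on {e.parent!r}", loc)

    g = model.graph()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
        report.add("error", "cycle", f"graph contains a cycle: {path}", path)

    for n in model.nodes:
        cpt = model.cpts.get(n.name)
        if cpt is None:
            report.add("error", "missing_cpt", f"node {n.name!r} has no CPT", n.name)
            continue
        graph_parents = model.parents_of(n.name)
        if list(cpt.parents) != graph_parents:
            report.add(
                "error",
                "parent_mismatch",
                f"CPT for {n.name!r} lists parents {list(cpt.parents)} "
                f"but the graph gives {graph_parents}",
                n.name,
            )
            continue
        if cycle:  # row counts are meaningless on a cyclic graph
            continue
        expected_rows = 1
        for p in cpt.parents:
            expected_rows *= model.node(p).cardinality
        if cpt.rows.shape != (expected_rows, n.cardinality):
            report.add(
                "error",
                "row_count",
                f"CPT for {n.name!r} has shape {cpt.rows.shape}; "
                f"expected ({expected_rows}, {n.cardinality})",
                n.name,
            )
            continue
        if np.any(cpt.rows < 0) or np.any(cpt.rows > 1):
            report.add("error", "probability_range", f"CPT for {n.name!r} has entries outside [0, 1]", n.name)
        sums = cpt.rows.sum(axis=1)
        for i in np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]:
            report.add(
                "error",
                "normalization",
                f"CPT for {n.name!r}, row {i}: probabilities sum to {sums[i]:.12g}, not 1",
                f"{n.name}[{i}]",
            )

    extra = set(model.cpts) - seen
    for name in sorted(extra):
        report.add("error", "extra_cpt", f"CPT for unknown node {name!r}", name)

    return report


def compile_cpt(rules: list[CPTRule], child: NodeSpec, parents: list[NodeSpec]) -> CPT:
    """Expand wildcard rules into a full CPT over all parent combinations.

    For each combination the unique most-specific matching rule supplies the
    row.  Two equally specific matching rules with *different* distributions
    raise :class:`AmbiguityError` (identical duplicates are tolerated); a
    combination matched by no rule raises :class:`CoverageError`.  The result
    is independent of rule-list order.
    """
    parent_names = {p.name for p in parents}
    for r in rules:
        if r.child != child.name:
            raise ModelError(f"rule for {r.child!r} passed to compile_cpt of {child.name!r}")
        for pname, pstate in r.pattern:
            if pname not in parent_names:
                raise ModelError(
                    f"rule for {child.name!r} constrains {pname!r}, which is not a parent"
                )
            spec = next(p for p in parents if p.name == pname)
            spec.state_index(pstate)  # validates the label
        dist = r.distribution_map
        if set(dist) != set(child.states):
            raise ModelError(
                f"rule for {child.name!r}: distribution states {sorted(dist)} "
                f"do not match node states {list(child.states)}"
            )
        total = sum(dist.values())
        if any(v < 0 or v > 1 for v in dist.values()) or abs(total - 1.0) > ROW_SUM_TOL:
            raise ModelError(
                f"rule for {child.name!r} with pattern {dict(r.pattern)}: "
                f"distribution sums to {total:.12g}"
            )

    n_rows = 1
    for p in parents:
        n_rows *= p.cardinality
    rows = np.empty((n_rows, child.cardinality), dtype=float)

    state_lists = [p.states for p in parents]
    for combo_states in itertools.product(*state_lists) if parents else [()]:
        combo = dict(zip([p.name for p in parents], combo_states))
        matching = [r for r in rules if r.matches(combo)]
        if not matching:
            raise CoverageError(
                f"no rule for {child.name!r} covers parent combination {combo}"
            )
        best = max(r.specificity for r in matching)
        winners = {r.distribution for r in matching if r.specificity == best}
        if len(winners) > 1:
            raise AmbiguityError(
                f"two rules of specificity {best} with different distributions "
                f"match {combo} for child {child.name!r}"
            )
        dist = dict(next(iter(winners)))
        idx = row_index(parents, combo) if parents else 0
        rows[idx] = [dist[s] for s in child.states]

    return CPT(child=child.name, parents=tuple(p.name for p in parents), rows=rows)


def joint_probability(model: BayesianNetworkModel, assignment: dict[str, str]) -> float:
    """Joint probability of a *full* assignment, ``prod_i P(xi | pa_i)``."""
    missing = set(model.node_names) - set(assignment)
    if missing:
        raise ModelError(f"assignment is missing nodes: {sorted(missing)}")
    unknown = set(assignment) - set(model.node_names)
    if unknown:
        raise ModelError(f"assignment names unknown nodes: {sorted(unknown)}")

    p = 1.0
    for node in model.nodes:
        cpt = model.cpts[node.name]
        parent_specs = [model.node(q) for q in cpt.parents]
        r = row_index(parent_specs, assignment) if parent_specs else 0
        p *= cpt.rows[r, node.state_index(assignment[node.name])]
    return p
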