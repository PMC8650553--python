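"""Discrete Bayesian networks with exact inference.

A network is a directed acyclic graph of categorical (here, mostly
dichotomous) nodes, each carrying a conditional probability table (CPT).
Inference — marginal distributions and posteriors under hard evidence —
is exact, via sum-product variable elimination with a min-degree
elimination order.  Exactness does not depend on the order, only cost;
at the scale of this package (a few dozen binary nodes in a two-layer
converging DAG) any order is tractable.

CPT row-order contract
----------------------
Rows of a CPT enumerate the Cartesian product of the parent state spaces
with the **last** parent in ``parent_order`` varying fastest; parent
states are indexed in their declared order, and each row is a
probability vector over the child's states in declared order.  The same
ordering is used by the JSON document format (:func:`serialize_network`)
bit-exactly.

Probabilities are stored in linear space.  For long products (data
likelihoods) use :func:`log_joint_probability`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NodeSpec",
    "ConditionalProbabilityTable",
    "BayesianNetwork",
    "QueryResult",
    "NetworkError",
    "IncompleteAssignmentError",
    "InconsistentEvidenceError",
    "NetworkFormatError",
    "validate_network",
    "joint_probability",
    "log_joint_probability",
    "marginal",
    "posterior",
    "posterior_joint",
    "probability_of_evidence",
    "forward_sample",
    "serialize_network",
    "deserialize_network",
    "deserialize_structure",
    "serialize_structure",
]

#: probabilities below this are treated as exactly zero when normalizing
#: posteriors (evidence of smaller mass is considered inconsistent).
ZERO_EVIDENCE = 1e-300

ROW_NORM_TOL = 1e-9


class NetworkError(ValueError):
    """Base class for network construction and inference errors."""


class IncompleteAssignmentError(NetworkError):
    """A full joint assignment was required but some node was missing."""


class InconsistentEvidenceError(NetworkError):
    """The supplied evidence has (numerically) zero prior probability."""


class NetworkFormatError(NetworkError):
    """A serialized network document violates the format contract."""


@dataclass(frozen=True)
class NodeSpec:
    """A named categorical node: ordered states and ordered parents."""

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise NetworkError(
                f"node {self.name!r} has no state {label!r}; states are {self.states}"
            ) from None


class ConditionalProbabilityTable:
    """P(child | parents) as a dense (n_parent_configs, n_child_states) table.

    Parameters
    ----------
    child:
        Child node name.
    parent_order:
        Parent names in the order that defines the row enumeration
        (last parent varies fastest).
    table:
        Array of shape ``(prod(parent cardinalities), n_child_states)``.
        A parentless node carries its prior as a single-row table.
    """

    def __init__(self, child: str, parent_order: Sequence[str], table: np.ndarray):
        self.child = child
        self.parent_order = tuple(parent_order)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != 2:
            raise NetworkError(f"CPT for {child!r}: table must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.table.shape[0]

    @property
    def n_child_states(self) -> int:
        return self.table.shape[1]

    @staticmethod
    def row_strides(parent_cards: Sequence[int]) -> np.ndarray:
        """Strides such that row = sum(parent_state_index * stride)."""
        strides = np.ones(len(parent_cards), dtype=np.int64)
        for i in range(len(parent_cards) - 2, -1, -1):
            strides[i] = strides[i + 1] * parent_cards[i + 1]
        return strides

    def row_index(self, parent_state_indices: Sequence[int], parent_cards: Sequence[int]) -> int:
        strides = self.row_strides(parent_cards)
        return int(np.dot(np.asarray(parent_state_indices, dtype=np.int64), strides))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConditionalProbabilityTable)
            and self.child == other.child
            and self.parent_order == other.parent_order
            and self.table.shape == other.table.shape
            and np.array_equal(self.table, other.table)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CPT({self.child!r}, parents={self.parent_order}, rows={self.n_rows})"


class BayesianNetwork:
    """A DAG of :class:`NodeSpec` with one CPT per node."""

    def __init__(
        self,
        nodes: Iterable[NodeSpec],
        cpts: Iterable[ConditionalProbabilityTable],
    ):
        self.nodes: dict[str, NodeSpec] = {}
        for spec in nodes:
            if spec.name in self.nodes:
                raise NetworkError(f"duplicate node {spec.name!r}")
            self.nodes[spec.name] = spec
        self.cpts: dict[str, ConditionalProbabilityTable] = {}
        for cpt in cpts:
            if cpt.child in self.cpts:
                raise NetworkError(f"duplicate CPT for {cpt.child!r}")
            self.cpts[cpt.child] = cpt

    # -- basic accessors ------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    def card(self, name: str) -> int:
        return len(self.nodes[name].states)

    def parents(self, name: str) -> tuple[str, ...]:
        return self.nodes[name].parents

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(n for n, s in self.nodes.items() if name in s.parents)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        seen: set[str] = set()
        temp: set[str] = set()

        def visit(n: str) -> None:
            if n in seen:
                return
            if n in temp:
                raise NetworkError("parent graph contains a cycle")
            temp.add(n)
            for p in self.nodes[n].parents:
                if p in self.nodes:
                    visit(p)
            temp.discard(n)
            seen.add(n)
            order.append(n)

        for n in self.nodes:
            visit(n)
        return order

    def to_factor(self, name: str) -> "Factor":
        """The node's CPT as a factor over (parents..., node)."""
        spec = self.nodes[name]
        cpt = self.cpts[name]
        cards = [self.card(p) for p in cpt.parent_order] + [len(spec.states)]
        values = cpt.table.reshape(cards)
        return Factor(cpt.parent_order + (name,), values)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BayesianNetwork)
            and self.nodes == other.nodes
            and self.cpts == other.cpts
        )


@dataclass
class QueryResult:
    """A (possibly conditional) distribution over one node's states."""

    node: str
    states: tuple[str, ...]
    distribution: np.ndarray
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, state: str) -> float:
        return float(self.distribution[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.distribution)}


# ---------------------------------------------------------------------------
# Factors and variable elimination
# ---------------------------------------------------------------------------


@dataclass
class Factor:
    """A nonnegative table over a tuple of variables (one axis each)."""

    vars: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.vars = tuple(self.vars)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.vars):
            raise NetworkError("factor rank does not match variable count")


def _aligned(f: Factor, vars_: tuple[str, ...]) -> np.ndarray:
    """Broadcastable view of ``f.values`` in the axis order of ``vars_``."""
    present = [v for v in vars_ if v in f.vars]
    perm = [f.vars.index(v) for v in present]
    arr = np.transpose(f.values, perm)
    shape = []
    it = iter(arr.shape)
    for v in vars_:
        shape.append(next(it) if v in f.vars else 1)
    return arr.reshape(shape)


def factor_product(f1: Factor, f2: Factor) -> Factor:
    vars_ = tuple(dict.fromkeys(f1.vars + f2.vars))
    return Factor(vars_, _aligned(f1, vars_) * _aligned(f2, vars_))


def factor_sum_out(f: Factor, var: str) -> Factor:
    axis = f.vars.index(var)
    return Factor(f.vars[:axis] + f.vars[axis + 1 :], f.values.sum(axis=axis))


def factor_reduce(f: Factor, var: str, index: int) -> Factor:
    axis = f.vars.index(var)
    return Factor(f.vars[:axis] + f.vars[axis + 1 :], np.take(f.values, index, axis=axis))


def _check_evidence(network: BayesianNetwork, evidence: Mapping[str, str]) -> dict[str, int]:
    idx: dict[str, int] = {}
    for name, state in evidence.items():
        if name not in network.nodes:
            raise NetworkError(f"evidence names unknown node {name!r}")
        idx[name] = network.nodes[name].state_index(state)
    return idx

def _min_degree_order(factors: list[Factor], elim: set[str]) -> list[str]:
    """Min-degree heuristic on the factor interaction graph."""
    neighbors: dict[str, set[str]] = {v: set() for v in elim}
    for f in factors:
        for v in f.vars:
            if v in elim:
                neighbors[v].update(u for u in f.vars if u != v)
    order: list[str] = []
    remaining = set(elim)
    while remaining:
        v = min(remaining, key=lambda u: (len(neighbors[u] & remaining), u))
        order.append(v)
        remaining.discard(v)
        nbrs = neighbors[v] & remaining
        for a in nbrs:  # connect the fill-in clique
            neighbors[a].update(nbrs - {a})
    return order


def _eliminate(
    network: BayesianNetwork,
    query_vars: Sequence[str],
    evidence: Mapping[str, str],
) -> Factor:
    """Unnormalized factor over ``query_vars``; its sum is P(evidence)."""
    ev_idx = _check_evidence(network, evidence)
    factors: list[Factor] = []
    for name in network.nodes:
        f = network.to_factor(name)
        for v, i in ev_idx.items():
            if v in f.vars:
                f = factor_reduce(f, v, i)
        factors.append(f)
    elim = set(network.nodes) - set(query_vars) - set(ev_idx)
    for v in _min_degree_order(factors, elim):
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = factor_product(prod, f)
        rest.append(factor_sum_out(prod, v))
        factors = rest
    result = Factor((), np.array(1.0).reshape(()))
    for f in factors:
        result = factor_product(result, f)
    # canonical axis order = query order
    order = tuple(v for v in query_vars if v in result.vars)
    perm = [result.vars.index(v) for v in order]
    return Factor(order, np.transpose(result.values, perm))


def probability_of_evidence(network: BayesianNetwork, evidence: Mapping[str, str]) -> float:
    """Exact P(evidence), marginalizing all other nodes."""
    return float(_eliminate(network, (), evidence).values)


def posterior_joint(
    network: BayesianNetwork,
    query_vars: Sequence[str],
    evidence: Mapping[str, str] | None = None,
) -> Factor:
    """Normalized joint posterior factor over ``query_vars`` given evidence."""
    evidence = dict(evidence or {})
    overlap = [v for v in query_vars if v in evidence]
    if overlap:
        raise NetworkError(f"query variables {overlap} appear in the evidence")
    f = _eliminate(network, tuple(query_vars), evidence)
    z = f.values.sum()
    if not z > ZERO_EVIDENCE:
        raise InconsistentEvidenceError(
            f"evidence {evidence!r} has zero probability under the network"
        )
    return Factor(f.vars, f.values / z)


def posterior(
    network: BayesianNetwork,
    node: str,
    evidence: Mapping[str, str] | None = None,
) -> QueryResult:
    """Exact P(node | evidence).

    Querying an evidence node returns its indicator distribution.
    """
    evidence = dict(evidence or {})
    if node not in network.nodes:
        raise NetworkError(f"unknown node {node!r}")
    spec = network.nodes[node]
    if node in evidence:
        dist = np.zeros(len(spec.states))
        dist[spec.state_index(evidence[node])] = 1.0
        # still reject impossible evidence
        if len(evidence) > 0 and not probability_of_evidence(network, evidence) > ZERO_EVIDENCE:
            raise InconsistentEvidenceError(f"evidence {evidence!r} has zero probability")
        return QueryResult(node, spec.states, dist, evidence)
    f = posterior_joint(network, (node,), evidence)
    return QueryResult(node, spec.states, f.values, evidence)


def marginal(network: BayesianNetwork, node: str) -> QueryResult:
    """Exact marginal distribution of ``node``."""
    return posterior(network, node, {})


# ---------------------------------------------------------------------------
# Joint probability of full assignments
# ---------------------------------------------------------------------------


def _full_assignment_indices(
    network: BayesianNetwork, assignment: Mapping[str, str]
) -> dict[str, int]:
    missing = [n for n in network.nodes if n not in assignment]
    if missing:
        raise IncompleteAssignmentError(f"assignment misses nodes {missing}")
    return {n: network.nodes[n].state_index(assignment[n]) for n in network.nodes}


def joint_probability(network: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """Chain-rule product of CPT entries for a full assignment."""
    idx = _full_assignment_indices(network, assignment)
    p = 1.0
    for name, spec in network.nodes.items():
        cpt = network.cpts[name]
        cards = [network.card(par) for par in cpt.parent_order]
        row = cpt.row_index([idx[par] for par in cpt.parent_order], cards)
        p *= cpt.table[row, idx[name]]
    return float(p)


def log_joint_probability(network: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """Log-space variant of :func:`joint_probability` (−inf on zero entries)."""
    idx = _full_assignment_indices(network, assignment)
    logp = 0.0
    for name in network.nodes:
        cpt = network.cpts[name]
        cards = [network.card(par) for par in cpt.parent_order]
        row = cpt.row_index([idx[par] for par in cpt.parent_order], cards)
        entry = cpt.table[row, idx[name]]
        if entry <= 0.0:
            return -math.inf
        logp += math.log(entry)
    return logp


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_network(network: BayesianNetwork) -> list[str]:
    """All invariant violations as human-readable strings (empty = valid)."""
    problems: list[str] = []
    for name, spec in network.nodes.items():
        if len(set(spec.states)) != len(spec.states):
            problems.append(f"node {name!r}: duplicate state labels")
        if name in spec.parents:
            problems.append(f"node {name!r}: lists itself as parent")
        for p in spec.parents:
            if p not in network.nodes:
                problems.append(f"node {name!r}: unknown parent {p!r}")
    try:
        network.topological_order()
    except NetworkError:
        problems.append("cycle: parent graph is not acyclic")
    if set(network.cpts) != set(network.nodes):
        extra = set(network.cpts) - set(network.nodes)
        miss = set(network.nodes) - set(network.cpts)
        if miss:
            problems.append(f"missing CPTs for nodes {sorted(miss)}")
        if extra:
            problems.append(f"CPTs for undeclared nodes {sorted(extra)}")
    for name, cpt in network.cpts.items():
        if name not in network.nodes:
            continue
        spec = network.nodes[name]
        if cpt.parent_order != spec.parents:
            problems.append(
                f"CPT for {name!r}: parent_order {cpt.parent_order} does not match "
                f"declared parents {spec.parents}"
            )
            continue
        if any(p not in network.nodes for p in cpt.parent_order):
            continue
        expected_rows = int(np.prod([network.card(p) for p in cpt.parent_order], dtype=np.int64))
        if cpt.n_rows != expected_rows:
            problems.append(
                f"CPT for {name!r}: {cpt.n_rows} rows, expected {expected_rows} "
                "(incomplete parent-configuration enumeration)"
            )
        if cpt.n_child_states != len(spec.states):
            problems.append(f"CPT for {name!r}: column count != number of child states")
            continue
        if np.any(cpt.table < 0) or np.any(cpt.table > 1):
            problems.append(f"CPT for {name!r}: entries outside [0, 1]")
        bad = np.where(np.abs(cpt.table.sum(axis=1) - 1.0) > ROW_NORM_TOL)[0]
        for r in bad[:5]:
            problems.append(f"CPT for {name!r}: row {int(r)} not normalized")
    return problems


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------


def forward_sample(network: BayesianNetwork, n: int, rng: np.random.Generator):
    """Ancestral sampling: n joint draws as a DataFrame of state labels."""
    import pandas as pd

    order = network.topological_order()
    drawn: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for name in order:
        spec = network.nodes[name]
        cpt = network.cpts[name]
        cards = [network.card(p) for p in cpt.parent_order]
        if cpt.parent_order:
            strides = ConditionalProbabilityTable.row_strides(cards)
            rows = np.zeros(n, dtype=np.int64)
            for p, s in zip(cpt.parent_order, strides):
                rows += drawn[p] * s
        else:
            rows = np.zeros(n, dtype=np.int64)
        probs = cpt.table[rows]  # (n, n_states)
        u = rng.random(n)
        idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        idx = np.minimum(idx, len(spec.states) - 1)
        drawn[name] = idx
        out[name] = np.asarray(spec.states, dtype=object)[idx]
    return pd.DataFrame({name: out[name] for name in network.nodes})


# ---------------------------------------------------------------------------
# Serialization (JSON document)
# ---------------------------------------------------------------------------

_FORMAT_NOTE = (
    "CPT rows enumerate parent configurations with the LAST parent in "
    "parent_order varying fastest; parent states indexed in declared order; "
    "each row is a probability vector in declared child-state order."
)


def serialize_network(network: BayesianNetwork) -> str:
    """Network as a JSON document honoring the row-order contract."""
    doc = {
        "format": _FORMAT_NOTE,
        "nodes": [
            {"name": s.name, "states": list(s.states), "parents": list(s.parents)}
            for s in network.nodes.values()
        ],
        "cpts": [
            {
                "child": c.child,
                "parent_order": list(c.parent_order),
                "rows": [[float(x) for x in row] for row in c.table],
            }
            for c in network.cpts.values()
        ],
    }
    return json.dumps(doc, indent=1)


def serialize_structure(specs: Sequence[NodeSpec]) -> str:
    """Nodes-only document (structure without parameters)."""
    doc = {
        "format": _FORMAT_NOTE,
        "nodes": [
            {"name": s.name, "states": list(s.states), "parents": list(s.parents)}
            for s in specs
        ],
    }
    return json.dumps(doc, indent=1)


def _parse_nodes(doc: dict) -> list[NodeSpec]:
    if "nodes" not in doc:
        raise NetworkFormatError("document has no 'nodes' field")
    specs = []
    for entry in doc["nodes"]:
        try:
            specs.append(
                NodeSpec(entry["name"], tuple(entry["states"]), tuple(entry.get("parents", ())))
            )
        except (KeyError, TypeError) as exc:
            raise NetworkFormatError(f"malformed node entry {entry!r}") from exc
    names = {s.name for s in specs}
    for s in specs:
        for p in s.parents:
            if p not in names:
                raise NetworkFormatError(f"node {s.name!r}: unknown parent reference {p!r}")
    return specs


def deserialize_structure(text: str) -> list[NodeSpec]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkFormatError(f"malformed document: {exc}") from exc
    return _parse_nodes(doc)


def deserialize_network(text: str) -> BayesianNetwork:
    """Parse a JSON network document; strict about the row-order contract.

    Parent lists in a CPT must match the node declaration exactly
    (reordering is rejected rather than canonicalized, so that the row
    enumeration stays bit-exact).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkFormatError(f"malformed document: {exc}") from exc
    specs = _parse_nodes(doc)
    by_name = {s.name: s for s in specs}
    cards = {s.name: len(s.states) for s in specs}
    cpts = []
    for entry in doc.get("cpts", []):
        child = entry.get("child")
        if child not in by_name:
            raise NetworkFormatError(f"CPT for undeclared node {child!r}")
        parent_order = tuple(entry.get("parent_order", ()))
        if parent_order != by_name[child].parents:
            raise NetworkFormatError(
                f"CPT for {child!r}: parent_order {parent_order} does not match the "
                f"declared parents {by_name[child].parents} (reordering is not accepted)"
            )
        rows = entry.get("rows", [])
        expected = int(np.prod([cards[p] for p in parent_order], dtype=np.int64))
        if len(rows) != expected:
            # name one missing configuration to aid debugging
            msg = f"CPT for {child!r}: {len(rows)} rows, expected {expected}"
            if len(rows) < expected:
                combos = itertools.product(*(by_name[p].states for p in parent_order))
                missing_cfg = next(itertools.islice(combos, len(rows), None))
                msg += f"; first missing parent configuration: {dict(zip(parent_order, missing_cfg))}"
            raise NetworkFormatError(msg)
        table = np.asarray(rows, dtype=float)
        if table.ndim != 2 or table.shape[1] != cards[child]:
            raise NetworkFormatError(f"CPT for {child!r}: rows are not vectors over child states")
        if np.any(np.abs(table.sum(axis=1) - 1.0) > ROW_NORM_TOL):
            raise NetworkFormatError(f"CPT for {child!r}: row not normalized")
        if np.any(table < 0) or np.any(table > 1):
            raise NetworkFormatError(f"CPT for {child!r}: entries outside [0, 1]")
        cpts.append(ConditionalProbabilityTable(child, parent_order, table))
    missing = set(by_name) - {c.child for c in cpts}
    if missing:
        raise NetworkFormatError(f"document omits CPTs for nodes {sorted(missing)}")
    return BayesianNetwork(specs, cpts)
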