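"""Delta-p sensitivity ranking and parent→child strength-of-influence.

Delta-p here is the **relative percent change** of the target-state
probability when a factor is clamped to each of its states:

    change(s) = 100 * (P(target | factor = s) - P(target)) / P(target)

and factors are ranked by Variation = |low-state change| + |high-state
change|.  Influence of an edge parent→child measures the distance
between the child's conditional distributions as the parent switches
states, aggregated over the configurations of the child's other parents;
four aggregation metrics are exposed because no single canonical
definition exists (average total variation is the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BayesianNetwork, marginal, posterior

__all__ = [
    "SensitivityRow",
    "InfluenceEntry",
    "delta_p",
    "variation",
    "rank_factors",
    "influence_value",
    "influence_table",
    "INFLUENCE_METRICS",
]


def variation(low_change: float, high_change: float) -> float:
    """The ranking statistic: |low-state change| + |high-state change|."""
    return abs(low_change) + abs(high_change)

INFLUENCE_METRICS = ("avg_tv", "weighted_tv", "avg_euclidean", "max_tv")


@dataclass(frozen=True)
class SensitivityRow:
    factor: str
    low_change: float
    high_change: float
    variation: float
    rank: int


@dataclass(frozen=True)
class InfluenceEntry:
    parent: str
    child: str
    influence: float
    metric: str


def delta_p(
    network: BayesianNetwork,
    target_node: str,
    target_state: str,
    factor: str,
) -> tuple[float, float]:
    """(low-state, high-state) relative percent change of P(target_state).

    Requires a dichotomous factor distinct from the target; the two
    changes are reported in the factor's declared state order.
    """
    if factor == target_node:
        raise ValueError("delta-p of a node on itself is not defined")
    spec = network.nodes[factor]
    if len(spec.states) != 2:
        raise ValueError(f"factor {factor!r} is not dichotomous")
    base = marginal(network, target_node)[target_state]
    if base <= 0.0:
        raise ValueError(f"baseline P({target_node}={target_state}) is zero")
    changes = []
    for state in spec.states:
        p = posterior(network, target_node, {factor: state})[target_state]
        changes.append(100.0 * (p - base) / base)
    return changes[0], changes[1]


def rank_factors(
    network: BayesianNetwork,
    target_node: str,
    target_state: str,
    factors,
) -> pd.DataFrame:
    """Per-factor delta-p table ranked by descending Variation.

    Ties in Variation break alphabetically by factor name.  Columns:
    factor, low_pct, high_pct, variation, rank.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor required")
    rows = []
    for f in factors:
        low, high = delta_p(network, target_node, target_state, f)
        rows.append((f, low, high, variation(low, high)))
    df = pd.DataFrame(rows, columns=["factor", "low_pct", "high_pct", "variation"])
    df = df.sort_values(["variation", "factor"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def _other_config_weights(
    network: BayesianNetwork, child: str, parent: str
) -> np.ndarray:
    """Joint probabilities of the child's other-parent configurations."""
    from .network import posterior_joint

    cpt = network.cpts[child]
    others = [p for p in cpt.parent_order if p != parent]
    if not others:
        return np.ones(1)
    f = posterior_joint(network, others, {})
    return f.values.reshape(-1)


def influence_value(
    network: BayesianNetwork,
    parent: str,
    child: str,
    metric: str = "avg_tv",
) -> InfluenceEntry:
    """Strength of influence of an existing edge parent→child.

    For every configuration of the child's other parents, the distance
    between the child distributions under the parent's states is taken
    (total variation, or Euclidean for ``avg_euclidean``); distances are
    aggregated by unweighted average (``avg_*``), by average weighted
    with the other-configurations' joint probability (``weighted_tv``),
    or by maximum (``max_tv``).  Zero iff the parent never alters the
    child's conditional distribution.
    """
    if metric not in INFLUENCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {INFLUENCE_METRICS}")
    cpt = network.cpts.get(child)
    if cpt is None or parent not in cpt.parent_order:
        raise ValueError(f"no edge {parent!r} -> {child!r} in the network")
    cards = [network.card(p) for p in cpt.parent_order]
    axis = cpt.parent_order.index(parent)
    # reshape rows into one axis per parent, child states last
    cube = cpt.table.reshape(cards + [cpt.n_child_states])
    cube = np.moveaxis(cube, axis, 0)  # parent axis first
    k = cube.shape[0]
    flat = cube.reshape(k, -1, cpt.n_child_states)  # (parent states, other configs, child)
    # pairwise distances across parent states, per other-config
    dists = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = flat[i] - flat[j]
            if metric == "avg_euclidean":
                d = np.sqrt((diff**2).sum(axis=1))
            else:
                d = 0.5 * np.abs(diff).sum(axis=1)
            dists.append(d)
    per_config = np.max(dists, axis=0) if len(dists) > 1 else dists[0]
    if metric == "weighted_tv":
        # per_config axes follow cpt.parent_order minus the parent — the same
        # order (and C-flattening) used by _other_config_weights
        weights = _other_config_weights(network, child, parent)
        # per_config is ordered with the parent axis removed from the front,
        # i.e. remaining axes in cpt order minus parent — same as weights
        value = float(np.dot(weights, per_config))
    elif metric == "max_tv":
        value = float(per_config.max())
    else:
        value = float(per_config.mean())
    return InfluenceEntry(parent, child, value, metric)


def influence_table(
    network: BayesianNetwork,
    edges=None,
    metric: str = "avg_tv",
) -> pd.DataFrame:
    """Influence values for a list of edges (default: all network edges),
    sorted by descending influence."""
    if edges is None:
        edges = [
            (p, child)
            for child, spec in network.nodes.items()
            for p in spec.parents
        ]
    rows = [influence_value(network, p, c, metric) for p, c in edges]
    df = pd.DataFrame(
        [(e.parent, e.child, e.influence, e.metric) for e in rows],
        columns=["parent", "child", "influence", "metric"],
    )
    return df.sort_values(
        ["influence", "parent", "child"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
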