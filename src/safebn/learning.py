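"""CPT estimation: maximum likelihood, EM with missing cells, noisy-OR.

Given an elicited structure (node specs) and a discretized dataset, each
node's CPT is estimated from (expected) family counts with optional
Dirichlet-style pseudocount smoothing.  Records with missing cells are
handled by expectation-maximization: the E-step computes, per record, the
exact posterior over the missing members of each node family given the
record's observed cells (via variable elimination on the current model),
and the M-step re-estimates CPTs from the expected counts.

A node with many parents (the 16-parent composite job-stress node) is
unestimable as a full table from ~1500 subjects; for such nodes a
noisy-OR parameterization (one leak plus one inhibition parameter per
parent, fitted by weighted maximum likelihood) is used by default and
expanded to a dense table for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .network import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    NodeSpec,
    posterior_joint,
    probability_of_evidence,
)

__all__ = [
    "LearningConfig",
    "LearnedModel",
    "mle_cpt",
    "em_learn",
    "log_likelihood",
    "fit_noisy_or",
    "noisy_or_table",
]


@dataclass(frozen=True)
class LearningConfig:
    """Estimation settings.

    ``smoothing_pseudocount`` is added to every (family-configuration,
    child-state) cell; ``parameterization`` selects dense tables
    everywhere (``"full-table"``) or noisy-OR for nodes with at least
    ``noisy_or_min_parents`` binary parents (``"noisy-or"``, default).
    EM is restarted ``multi_start`` times from jittered uniform tables,
    keeping the best final objective.
    """

    smoothing_pseudocount: float = 1.0
    em_tolerance: float = 1e-6
    em_max_iter: int = 500
    parameterization: str = "noisy-or"
    noisy_or_min_parents: int = 9
    multi_start: int = 3
    init_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_pseudocount < 0:
            raise ValueError("smoothing_pseudocount must be >= 0")
        if self.em_tolerance <= 0:
            raise ValueError("em_tolerance must be > 0")
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be >= 1")
        if self.parameterization not in ("full-table", "noisy-or"):
            raise ValueError("parameterization must be 'full-table' or 'noisy-or'")


@dataclass
class LearnedModel:
    network: BayesianNetwork
    log_likelihood: float
    iterations: int
    converged: bool
    config: LearningConfig
    n_starts: int = 1


# ---------------------------------------------------------------------------
# Family indexing helpers
# ---------------------------------------------------------------------------


def _state_indices(spec: NodeSpec, column: pd.Series) -> np.ndarray:
    """Map a label column to state indices; missing -> -1."""
    lookup = {s: i for i, s in enumerate(spec.states)}
    out = np.full(len(column), -1, dtype=np.int64)
    vals = column.to_numpy(dtype=object)
    for label, i in lookup.items():
        out[vals == label] = i
    bad = (out == -1) & ~pd.isna(vals)
    if bad.any():
        offending = sorted({v for v in vals[bad]})
        raise ValueError(
            f"column {spec.name!r} has labels {offending} outside states {spec.states}"
        )
    return out


def _family_counts(
    spec: NodeSpec,
    idx: Mapping[str, np.ndarray],
    cards: Mapping[str, int],
    rows_mask: np.ndarray,
) -> np.ndarray:
    """Exact counts over (parent config, child state) for fully observed rows."""
    n_rows = int(np.prod([cards[p] for p in spec.parents], dtype=np.int64))
    n_states = cards[spec.name]
    counts = np.zeros((n_rows, n_states))
    sel = np.where(rows_mask)[0]
    if sel.size == 0:
        return counts
    strides = ConditionalProbabilityTable.row_strides([cards[p] for p in spec.parents])
    config = np.zeros(sel.size, dtype=np.int64)
    for p, s in zip(spec.parents, strides):
        config += idx[p][sel] * s
    flat = config * n_states + idx[spec.name][sel]
    counts += np.bincount(flat, minlength=n_rows * n_states).reshape(n_rows, n_states)
    return counts


def _decode_configs(rows: np.ndarray, cards: Sequence[int]) -> np.ndarray:
    """Inverse of the row-index encoding: (len(rows), k) state indices."""
    k = len(cards)
    out = np.zeros((rows.size, k), dtype=np.int64)
    strides = ConditionalProbabilityTable.row_strides(cards)
    rem = rows.copy()
    for j in range(k):
        out[:, j] = rem // strides[j]
        rem = rem % strides[j]
    return out


# ---------------------------------------------------------------------------
# Noisy-OR
# ---------------------------------------------------------------------------


def noisy_or_table(leak: float, inhibitions: Sequence[float], event_index: int = 1) -> np.ndarray:
    """Dense CPT of a binary noisy-OR child over binary parents.

    ``P(child = event | parents) = 1 - (1 - leak) * prod_j (1 - w_j)``
    over parents in their active state (state index 1).  Rows follow the
    package row-order contract (last parent fastest).
    """
    w = np.asarray(inhibitions, dtype=float)
    k = w.size
    rows = np.arange(2**k, dtype=np.int64)
    active = _decode_configs(rows, [2] * k)  # (2^k, k) of 0/1
    log_keep = np.log1p(-np.clip(w, 0.0, 1.0 - 1e-12))
    p_event = 1.0 - (1.0 - leak) * np.exp(active @ log_keep)
    table = np.empty((2**k, 2))
    table[:, event_index] = p_event
    table[:, 1 - event_index] = 1.0 - p_event
    return table


def fit_noisy_or(
    parent_states: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    event_index: int = 1,
) -> tuple[float, np.ndarray]:
    """Weighted ML fit of a noisy-OR leak and per-parent inhibitions.

    ``parent_states`` is an (n, k) 0/1 matrix (1 = active), ``event`` an
    n-vector of 0/1 child outcomes.  Parameters are optimized on the
    logit scale with L-BFGS.
    """
    x = np.asarray(parent_states, dtype=float)
    y = np.asarray(event, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n, k = x.shape

    def nll(theta: np.ndarray) -> float:
        leak = expit(theta[0])
        keep = np.log1p(-expit(theta[1:]))  # log(1 - w_j)
        s = np.log1p(-leak) + x @ keep  # log P(no event)
        p = -np.expm1(s)
        p = np.clip(p, 1e-12, 1.0)
        return float(-(w * (y * np.log(p) + (1 - y) * s)).sum())

    theta0 = np.concatenate([[-1.0], np.full(k, -1.0)])
    res = minimize(nll, theta0, method="L-BFGS-B")
    leak = float(expit(res.x[0]))
    inhib = expit(res.x[1:])
    return leak, np.asarray(inhib)


def _fit_noisy_or_from_counts(spec: NodeSpec, counts: np.ndarray, event_index: int = 1):
    """Fit noisy-OR from an expected-count matrix (n_configs, 2)."""
    nz = np.where(counts.sum(axis=1) > 0)[0]
    configs = _decode_configs(nz, [2] * len(spec.parents)).astype(float)
    x = np.vstack([configs, configs])
    y = np.concatenate([np.ones(nz.size), np.zeros(nz.size)])
    w = np.concatenate([counts[nz, event_index], counts[nz, 1 - event_index]])
    keep = w > 0
    leak, inhib = fit_noisy_or(x[keep], y[keep], w[keep], event_index)
    return noisy_or_table(leak, inhib, event_index)


def _is_noisy_or_node(spec: NodeSpec, cards: Mapping[str, int], config: LearningConfig) -> bool:
    return (
        config.parameterization == "noisy-or"
        and len(spec.parents) >= config.noisy_or_min_parents
        and cards[spec.name] == 2
        and all(cards[p] == 2 for p in spec.parents)
    )


# ---------------------------------------------------------------------------
# Maximum likelihood (complete data)
# ---------------------------------------------------------------------------


def _counts_to_table(counts: np.ndarray, smoothing: float, node: str) -> np.ndarray:
    table = counts + smoothing
    row_sums = table.sum(axis=1, keepdims=True)
    zero = (row_sums == 0).ravel()
    if zero.any():
        warnings.warn(
            f"node {node!r}: {int(zero.sum())} parent configurations unobserved with "
            "zero smoothing; those rows set to uniform"
        )
        table[zero] = 1.0
        row_sums = table.sum(axis=1, keepdims=True)
    return table / row_sums


def mle_cpt(
    structure: Sequence[NodeSpec],
    data: pd.DataFrame,
    smoothing: float = 0.0,
    config: LearningConfig | None = None,
) -> BayesianNetwork:
    """Closed-form CPT estimation from complete discretized data.

    Each entry is ``(count(child, parents) + lambda) / (count(parents) +
    lambda * n_states)``.  With ``lambda = 0``, unobserved parent
    configurations produce uniform rows and a warning.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    cards = {s.name: len(s.states) for s in structure}
    idx = {s.name: _state_indices(s, data[s.name]) for s in structure}
    if any((idx[s.name] < 0).any() for s in structure):
        raise ValueError("data contain missing cells; use em_learn")
    all_rows = np.ones(len(data), dtype=bool)
    nor_cfg = config or LearningConfig(parameterization="full-table")
    cpts = []
    for spec in structure:
        counts = _family_counts(spec, idx, cards, all_rows)
        if _is_noisy_or_node(spec, cards, nor_cfg):
            table = _fit_noisy_or_from_counts(spec, counts)
        else:
            table = _counts_to_table(counts, smoothing, spec.name)
        cpts.append(ConditionalProbabilityTable(spec.name, spec.parents, table))
    return BayesianNetwork(structure, cpts)


# ---------------------------------------------------------------------------
# Log-likelihood of (possibly incomplete) data
# ---------------------------------------------------------------------------


def _pattern_groups(data: pd.DataFrame, columns: Sequence[str]):
    """Group rows by their full observed-value tuple (NaN = missing)."""
    vals = data[list(columns)].to_numpy(dtype=object)
    keys: dict[tuple, list[int]] = {}
    for i in range(vals.shape[0]):
        key = tuple(
            None if pd.isna(v) else v for v in vals[i]
        )
        keys.setdefault(key, []).append(i)
    return keys


def log_likelihood(network: BayesianNetwork, data: pd.DataFrame) -> float:
    """Sum over records of log P(observed cells), exact marginalization.

    Records of zero likelihood contribute −inf and are reported in a
    warning with their positional indices.
    """
    columns = [n for n in network.nodes if n in data.columns]
    cards = {n: network.card(n) for n in columns}
    complete_mask = ~data[columns].isna().any(axis=1).to_numpy()
    total = 0.0
    bad: list[int] = []
    if complete_mask.any():
        idx = {
            n: _state_indices(network.nodes[n], data[n])
            for n in columns
        }
        sel = np.where(complete_mask)[0]
        logp = np.zeros(sel.size)
        for n in columns:
            cpt = network.cpts[n]
            strides = ConditionalProbabilityTable.row_strides(
                [cards[p] for p in cpt.parent_order]
            )
            rows = np.zeros(sel.size, dtype=np.int64)
            for p, s in zip(cpt.parent_order, strides):
                rows += idx[p][sel] * s
            entries = cpt.table[rows, idx[n][sel]]
            with np.errstate(divide="ignore"):
                logp += np.log(entries)
        if np.isneginf(logp).any():
            bad.extend(sel[np.isneginf(logp)].tolist())
        total += float(logp[~np.isneginf(logp)].sum())
    incomplete = data[~complete_mask] if (~complete_mask).any() else None
    if incomplete is not None:
        for key, rows in _pattern_groups(incomplete, columns).items():
            evidence = {c: v for c, v in zip(columns, key) if v is not None}
            p = probability_of_evidence(network, evidence) if evidence else 1.0
            if p <= 0.0:
                bad.extend(incomplete.index[rows].tolist())
            else:
                total += len(rows) * float(np.log(p))
    if bad:
        warnings.warn(f"records with zero likelihood: {bad[:20]}")
        return -np.inf
    return total


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _log_prior(network: BayesianNetwork, smoothing: float) -> float:
    if smoothing == 0:
        return 0.0
    lp = 0.0
    for cpt in network.cpts.values():
        with np.errstate(divide="ignore"):
            logs = np.log(np.clip(cpt.table, 1e-300, 1.0))
        lp += smoothing * float(logs.sum())
    return lp


def _init_network(
    structure: Sequence[NodeSpec], cards: Mapping[str, int], jitter: float, rng
) -> BayesianNetwork:
    """Uniform CPTs plus symmetric Dirichlet jitter."""
    cpts = []
    for spec in structure:
        n_rows = int(np.prod([cards[p] for p in spec.parents], dtype=np.int64))
        k = cards[spec.name]
        table = np.full((n_rows, k), 1.0 / k)
        if jitter > 0:
            table = rng.dirichlet(np.full(k, 1.0 / max(jitter, 1e-6)), size=n_rows)
        cpts.append(ConditionalProbabilityTable(spec.name, spec.parents, table))
    return BayesianNetwork(structure, cpts)


def em_learn(
    structure: Sequence[NodeSpec],
    data: pd.DataFrame,
    config: LearningConfig | None = None,
) -> LearnedModel:
    """EM parameter estimation over (possibly incomplete) discrete records.

    With fully observed data this reduces to :func:`mle_cpt` in a single
    iteration.  The ascended objective (observed-data log-likelihood plus
    the pseudocount log-prior when smoothing is nonzero) is asserted
    non-decreasing at every iteration.
    """
    config = config or LearningConfig()
    if len(data) == 0:
        raise ValueError("empty dataset")
    cards = {s.name: len(s.states) for s in structure}
    columns = [s.name for s in structure]
    missing_cols = [c for c in columns if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data misses columns {missing_cols}")

    na = data[columns].isna()
    if not na.any().any():
        net = mle_cpt(structure, data, config.smoothing_pseudocount, config)
        ll = log_likelihood(net, data)
        return LearnedModel(net, ll, 1, True, config, n_starts=1)

    if not (~na.any(axis=1)).any():
        warnings.warn("no fully observed record; EM may be poorly identified")

    idx = {s.name: _state_indices(s, data[s.name]) for s in structure}
    # per family: rows where the whole family is observed can be counted once
    base_counts: dict[str, np.ndarray] = {}
    family_incomplete_rows: dict[str, np.ndarray] = {}
    for spec in structure:
        fam = list(spec.parents) + [spec.name]
        fam_obs = ~na[fam].any(axis=1).to_numpy()
        base_counts[spec.name] = _family_counts(spec, idx, cards, fam_obs)
        family_incomplete_rows[spec.name] = np.where(~fam_obs)[0]

    any_family_incomplete = sorted(
        {int(r) for rows in family_incomplete_rows.values() for r in rows}
    )
    sub = data.iloc[any_family_incomplete]
    pattern_rows = _pattern_groups(sub, columns)
    col_pos = {c: i for i, c in enumerate(columns)}
    spec_by_name = {s.name: s for s in structure}

    best: LearnedModel | None = None
    n_starts = max(1, config.multi_start)
    for start in range(n_starts):
        rng = np.random.default_rng(config.seed + start)
        net = _init_network(structure, cards, config.init_jitter, rng)
        prev_obj = -np.inf
        converged = False
        iterations = 0
        for it in range(1, config.em_max_iter + 1):
            iterations = it
            counts = {name: c.copy() for name, c in base_counts.items()}
            # E-step over the records with at least one incomplete family
            for key, rows in pattern_rows.items():
                weight = len(rows)
                observed = {c: v for c, v in zip(columns, key) if v is not None}
                missing_here = {c for c, v in zip(columns, key) if v is None}
                cache: dict[tuple, np.ndarray] = {}
                for spec in structure:
                    fam = list(spec.parents) + [spec.name]
                    fam_missing = tuple(v for v in fam if v in missing_here)
                    if not fam_missing:
                        continue
                    if fam_missing not in cache:
                        cache[fam_missing] = posterior_joint(
                            net, fam_missing, observed
                        ).values
                    q = cache[fam_missing]
                    strides = ConditionalProbabilityTable.row_strides(
                        [cards[p] for p in spec.parents]
                    )

                    def observed_index(var: str) -> int:
                        return spec_by_name[var].state_index(key[col_pos[var]])

                    for flat, prob in np.ndenumerate(q):
                        assign = dict(zip(fam_missing, flat))
                        row = 0
                        for p, s in zip(spec.parents, strides):
                            pi = assign[p] if p in assign else observed_index(p)
                            row += int(pi) * int(s)
                        ci = (
                            assign[spec.name]
                            if spec.name in assign
                            else observed_index(spec.name)
                        )
                        counts[spec.name][row, int(ci)] += weight * float(prob)
            # M-step
            cpts = []
            for spec in structure:
                if _is_noisy_or_node(spec, cards, config):
                    table = _fit_noisy_or_from_counts(spec, counts[spec.name])
                else:
                    table = _counts_to_table(
                        counts[spec.name], config.smoothing_pseudocount, spec.name
                    )
                cpts.append(ConditionalProbabilityTable(spec.name, spec.parents, table))
            net = BayesianNetwork(structure, cpts)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll = log_likelihood(net, data)
            obj = ll + _log_prior(net, config.smoothing_pseudocount)
            if obj + 1e-9 * (1 + abs(obj)) < prev_obj:
                raise RuntimeError(
                    f"EM objective decreased at iteration {it}: {prev_obj} -> {obj}"
                )
            if abs(obj - prev_obj) < config.em_tolerance:
                converged = True
                prev_obj = obj
                break
            prev_obj = obj
        model = LearnedModel(net, ll, iterations, converged, config, n_starts=n_starts)
        model._objective = prev_obj  # type: ignore[attr-defined]
        if best is None or prev_obj > best._objective:  # type: ignore[attr-defined]
            best = model
    if not best.converged:
        warnings.warn(f"EM did not converge in {config.em_max_iter} iterations")
    return best
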