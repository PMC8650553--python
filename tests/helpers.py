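"""Independent oracles shared by the test suite.

Everything here deliberately avoids the package's inference code paths:
joint probabilities are computed by explicit enumeration with its own
row-index arithmetic, so that variable elimination can be checked against
an algorithmically independent reference.
"""

from __future__ import annotations

import itertools

import numpy as np

from safebn.network import BayesianNetwork, ConditionalProbabilityTable, NodeSpec


def brute_joint(net: BayesianNetwork) -> dict[tuple[str, ...], float]:
    """Full joint table by explicit enumeration (independent arithmetic)."""
    names = list(net.nodes)
    out: dict[tuple[str, ...], float] = {}
    for states in itertools.product(*(net.nodes[n].states for n in names)):
        a = dict(zip(names, states))
        p = 1.0
        for n in names:
            spec = net.nodes[n]
            cpt = net.cpts[n]
            row = 0
            for par in cpt.parent_order:  # last parent varies fastest
                row = row * len(net.nodes[par].states) + net.nodes[par].states.index(a[par])
            p *= cpt.table[row, spec.states.index(a[n])]
        out[states] = p
    return out


def brute_posterior(net: BayesianNetwork, node: str, evidence: dict[str, str]):
    """P(node | evidence) by summing the enumerated joint (Bayes' rule)."""
    names = list(net.nodes)
    joint = brute_joint(net)
    spec = net.nodes[node]
    numer = np.zeros(len(spec.states))
    denom = 0.0
    for states, p in joint.items():
        a = dict(zip(names, states))
        if any(a[k] != v for k, v in evidence.items()):
            continue
        denom += p
        numer[spec.states.index(a[node])] += p
    return numer / denom if denom > 0 else numer


def random_network(rng: np.random.Generator, n_nodes: int, max_parents: int = 3):
    """A random binary-node DAG with Dirichlet CPT rows."""
    names = [f"v{i}" for i in range(n_nodes)]
    specs = []
    cpts = []
    for i, name in enumerate(names):
        k = min(i, rng.integers(0, max_parents + 1))
        parents = tuple(rng.choice(names[:i], size=k, replace=False)) if k else ()
        specs.append(NodeSpec(name, ("s0", "s1"), parents))
        rows = rng.dirichlet((1.0, 1.0), size=2**k)
        cpts.append(ConditionalProbabilityTable(name, parents, rows))
    return BayesianNetwork(specs, cpts)


def random_mass(rng: np.random.Generator):
    """A random Dempster–Shafer mass over the 7 nonempty frame subsets."""
    from safebn.elicitation import FRAME, MassFunction

    subsets = [frozenset(s) for r in (1, 2, 3) for s in itertools.combinations(sorted(FRAME), r)]
    w = rng.dirichlet(np.ones(len(subsets)))
    return MassFunction(dict(zip(subsets, w)))
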