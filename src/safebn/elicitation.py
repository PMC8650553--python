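"""Dempster–Shafer combination of expert edge opinions and DAG assembly.

For every candidate pair of variables (A, B), each expert distributes one
unit of mass over nonempty subsets of the three-hypothesis frame

    F : A → B (forward edge)
    B : A ← B (backward edge)
    N : A ↑ B (no edge)

Opinions are fused with Dempster's rule of combination; the fused mass
function is reduced to an edge verdict with a configurable decision rule
(pignistic maximum by default), and the accepted edges are assembled into
a DAG, admitting edges in descending support order and skipping any whose
addition would create a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "FORWARD",
    "BACKWARD",
    "NO_EDGE",
    "FRAME",
    "MassFunction",
    "EdgeDecision",
    "StructureResult",
    "TotalConflictError",
    "dempster_combine",
    "decide_edge",
    "build_structure",
    "load_opinions",
    "opinions_to_frame",
    "decide_edges",
]

FORWARD = "F"
BACKWARD = "B"
NO_EDGE = "N"
FRAME: frozenset[str] = frozenset({FORWARD, BACKWARD, NO_EDGE})

_LETTER_ORDER = (FORWARD, BACKWARD, NO_EDGE)

MASS_TOL = 1e-9


class TotalConflictError(ValueError):
    """Dempster's rule is undefined: the sources fully contradict (K = 1)."""


def _as_subset(key) -> frozenset[str]:
    if isinstance(key, str):
        subset = frozenset(key)
    else:
        subset = frozenset(key)
    if not subset or not subset <= FRAME:
        raise ValueError(f"{key!r} is not a nonempty subset of the frame {set(FRAME)}")
    return subset


def encode_subset(subset: frozenset[str]) -> str:
    """Canonical text encoding: concatenation in F, B, N order."""
    return "".join(c for c in _LETTER_ORDER if c in subset)


@dataclass(frozen=True)
class MassFunction:
    """A basic probability assignment over nonempty subsets of the frame."""

    masses: dict

    def __post_init__(self) -> None:
        clean: dict[frozenset[str], float] = {}
        for key, value in self.masses.items():
            subset = _as_subset(key)
            v = float(value)
            if v < -MASS_TOL:
                raise ValueError(f"negative mass {v} on {encode_subset(subset)}")
            if v > 0.0:
                clean[subset] = clean.get(subset, 0.0) + v
        total = sum(clean.values())
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses sum to {total}, not 1")
        object.__setattr__(self, "masses", clean)

    @classmethod
    def vacuous(cls) -> "MassFunction":
        """Total ignorance: all mass on the whole frame."""
        return cls({FRAME: 1.0})

    def mass(self, subset) -> float:
        return self.masses.get(_as_subset(subset), 0.0)

    def belief(self, subset) -> float:
        """Bel(A) = sum of masses fully inside A."""
        a = _as_subset(subset)
        return sum(v for s, v in self.masses.items() if s <= a)

    def plausibility(self, subset) -> float:
        """Pl(A) = sum of masses not contradicting A."""
        a = _as_subset(subset)
        return sum(v for s, v in self.masses.items() if s & a)

    def pignistic(self) -> dict[str, float]:
        """BetP: each subset's mass split equally among its atoms."""
        bet = {h: 0.0 for h in _LETTER_ORDER}
        for s, v in self.masses.items():
            share = v / len(s)
            for h in s:
                bet[h] += share
        return bet

    def discount(self, reliability: float) -> "MassFunction":
        """Shafer discounting: scale masses by ``reliability``, move the rest
        to the whole frame (reliability 1 = fully credible expert)."""
        if not 0.0 <= reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")
        out: dict[frozenset[str], float] = {}
        for s, v in self.masses.items():
            out[s] = out.get(s, 0.0) + reliability * v
        out[FRAME] = out.get(FRAME, 0.0) + (1.0 - reliability)
        return MassFunction(out)


def _combine_with_conflict(m1: MassFunction, m2: MassFunction) -> tuple[MassFunction, float]:
    raw: dict[frozenset[str], float] = {}
    conflict = 0.0
    for s1, v1 in m1.masses.items():
        for s2, v2 in m2.masses.items():
            inter = s1 & s2
            if inter:
                raw[inter] = raw.get(inter, 0.0) + v1 * v2
            else:
                conflict += v1 * v2
    if conflict >= 1.0 - MASS_TOL:
        raise TotalConflictError("total conflict between sources (K = 1)")
    norm = 1.0 - conflict
    return MassFunction({s: v / norm for s, v in raw.items()}), conflict


def dempster_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination (commutative, associative)."""
    combined, _ = _combine_with_conflict(m1, m2)
    return combined


@dataclass
class EdgeDecision:
    """The fused verdict for one candidate pair."""

    pair: tuple[str, str]
    verdict: str  # FORWARD | BACKWARD | NO_EDGE
    support: float
    combined: MassFunction
    conflict: float  # cumulative normalization mass removed across combinations

    def as_edge(self) -> tuple[str, str] | None:
        a, b = self.pair
        if self.verdict == FORWARD:
            return (a, b)
        if self.verdict == BACKWARD:
            return (b, a)
        return None


def decide_edge(
    opinions: Sequence[MassFunction],
    pair: tuple[str, str] = ("A", "B"),
    rule: str = "pignistic",
    tie_break: Sequence[str] = (NO_EDGE, FORWARD, BACKWARD),
    reliabilities: Sequence[float] | None = None,
) -> EdgeDecision:
    """Fuse one pair's expert opinions and pick the winning hypothesis.

    ``rule`` scores atoms by pignistic probability (default), belief
    (``"belief"``) or plausibility (``"plausibility"``).  Ties are broken
    conservatively toward "no edge" first, then forward.
    """
    if not opinions:
        raise ValueError("at least one opinion is required")
    if reliabilities is not None:
        if len(reliabilities) != len(opinions):
            raise ValueError("one reliability per expert required")
        opinions = [m.discount(r) for m, r in zip(opinions, reliabilities)]
    combined = opinions[0]
    cum_keep = 1.0
    for m in opinions[1:]:
        combined, k = _combine_with_conflict(combined, m)
        cum_keep *= 1.0 - k
    conflict = 1.0 - cum_keep
    if rule == "pignistic":
        scores = combined.pignistic()
    elif rule == "belief":
        scores = {h: combined.belief({h}) for h in _LETTER_ORDER}
    elif rule == "plausibility":
        scores = {h: combined.plausibility({h}) for h in _LETTER_ORDER}
    else:
        raise ValueError(f"unknown decision rule {rule!r}")
    best = max(scores.values())
    # tolerance so that exact ties (e.g. the vacuous opinion) break as documented
    winners = [h for h in tie_break if scores[h] >= best - MASS_TOL]
    verdict = winners[0]
    return EdgeDecision(tuple(pair), verdict, scores[verdict], combined, conflict)


@dataclass
class StructureResult:
    """Accepted DAG edges plus the decisions skipped by the cycle guard."""

    edges: list[tuple[str, str]]
    skipped: list[EdgeDecision] = field(default_factory=list)


def build_structure(
    node_names: Iterable[str], decisions: Sequence[EdgeDecision]
) -> StructureResult:
    """Assemble an acyclic edge list from per-pair verdicts.

    Directed verdicts are admitted in descending support order (ties by
    pair name, deterministic); an edge whose addition would create a cycle
    is skipped and reported.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(node_names)
    accepted: list[tuple[str, str]] = []
    skipped: list[EdgeDecision] = []
    directed = [d for d in decisions if d.as_edge() is not None]
    for decision in sorted(directed, key=lambda d: (-d.support, d.pair)):
        u, v = decision.as_edge()
        graph.add_edge(u, v)
        if nx.is_directed_acyclic_graph(graph):
            accepted.append((u, v))
        else:
            graph.remove_edge(u, v)
            skipped.append(decision)
    return StructureResult(accepted, skipped)


# ---------------------------------------------------------------------------
# Expert-opinion table interface
# ---------------------------------------------------------------------------

_OPINION_COLUMNS = ("expert", "node_a", "node_b", "subset", "mass")


def load_opinions(source) -> pd.DataFrame:
    """Read a delimited expert-opinion table (one row per expert, pair, subset)."""
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source.copy()
    missing = [c for c in _OPINION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"opinion table misses columns {missing}")
    return df


def opinions_to_frame(df: pd.DataFrame) -> dict[tuple[str, str], list[MassFunction]]:
    """Group an opinion table into per-pair expert mass-function lists."""
    out: dict[tuple[str, str], list[MassFunction]] = {}
    for (a, b), pair_df in df.groupby(["node_a", "node_b"], sort=False):
        opinions = []
        for _, expert_df in pair_df.groupby("expert", sort=True):
            opinions.append(
                MassFunction({row.subset: row.mass for row in expert_df.itertuples()})
            )
        out[(a, b)] = opinions
    return out


def decide_edges(
    df: pd.DataFrame,
    rule: str = "pignistic",
    reliabilities: Mapping[str, float] | None = None,
) -> list[EdgeDecision]:
    """Fuse every pair in an opinion table into an :class:`EdgeDecision`."""
    decisions = []
    for (a, b), pair_df in df.groupby(["node_a", "node_b"], sort=False):
        opinions = []
        rels = []
        for expert, expert_df in pair_df.groupby("expert", sort=True):
            opinions.append(
                MassFunction({row.subset: row.mass for row in expert_df.itertuples()})
            )
            rels.append(1.0 if reliabilities is None else float(reliabilities.get(expert, 1.0)))
        decisions.append(
            decide_edge(opinions, pair=(a, b), rule=rule,
                        reliabilities=None if reliabilities is None else rels)
        )
    return decisions
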