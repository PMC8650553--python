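"""Canonical study objects: node names, calibrated core network, full structure.

The analysis concerns 1530 petrochemical workers described by 16 job-stress
scale scores (NIOSH GJSQ), 7 safety-climate dimension scores (NOSACQ-50),
two composite nodes (overall job stress, overall safety climate) and a
binary accident-history outcome.  All nodes are dichotomous after
uniform-width discretization.

Two network granularities are used throughout the package:

* the **core network** — job stress → safety climate, job stress →
  accident, safety climate → accident — whose accident CPT and priors are
  calibrated to the published figures (P(JS=high)=0.50, the safety-climate
  marginal 0.53, and the accident CPT with P(yes)=0.91/0.93/0.32/0.95 over
  (SC, JS) = (low,low), (low,high), (high,low), (high,high));
* the **full structure** — 16 scales → job stress; job stress → each of
  the 7 climate dimensions; the 7 dimensions → safety climate; job stress
  and safety climate → accident — whose parameters are learned from data.

``P(SC=high | JS=low)`` is not printed anywhere; it is solved from the
published safety-climate marginal:
``0.53 = 0.50 * 0.37 + 0.50 * x  =>  x = 0.69``.
"""

from __future__ import annotations

import pandas as pd

from .network import BayesianNetwork, ConditionalProbabilityTable, NodeSpec

__all__ = [
    "STRESS_SCALES",
    "CLIMATE_DIMENSIONS",
    "JOB_STRESS",
    "SAFETY_CLIMATE",
    "ACCIDENT",
    "LOW_HIGH",
    "ACCIDENT_STATES",
    "ACCIDENT_CPT_YES",
    "P_JS_HIGH",
    "P_SC_HIGH_GIVEN_JS_HIGH",
    "SC_MARGINAL_HIGH",
    "solve_sc_high_given_js_low",
    "core_network",
    "full_structure",
    "candidate_edges",
    "default_expert_opinions",
]

#: The 16 job-stress scales used as predictors (GJSQ scale mean-scores).
STRESS_SCALES: tuple[str, ...] = (
    "general_health",
    "employment_opportunity",
    "work_hazard",
    "other_health_information",
    "mental_demand",
    "your_job",
    "workload_responsibility",
    "job_requirement",
    "problems_at_work",
    "job_control",
    "job_satisfaction",
    "feel_about_yourself",
    "conflict_at_work",
    "social_support",
    "job_future",
    "physical_environment",
)

#: The 7 NOSACQ-50 safety-climate dimensions.
CLIMATE_DIMENSIONS: tuple[str, ...] = (
    "mgmt_safety_priority_ability",
    "mgmt_safety_empowerment",
    "mgmt_safety_justice",
    "worker_safety_commitment",
    "worker_safety_priority_risk",
    "peer_safety_communication",
    "worker_trust_safety_systems",
)

JOB_STRESS = "job_stress"
SAFETY_CLIMATE = "safety_climate"
ACCIDENT = "accident"

LOW_HIGH: tuple[str, str] = ("low", "high")
ACCIDENT_STATES: tuple[str, str] = ("yes", "no")  # published CPT column order

#: P(accident = yes | safety climate, job stress), keyed (SC state, JS state).
ACCIDENT_CPT_YES: dict[tuple[str, str], float] = {
    ("low", "low"): 0.91,
    ("low", "high"): 0.93,
    ("high", "low"): 0.32,
    ("high", "high"): 0.95,
}

P_JS_HIGH = 0.50
P_SC_HIGH_GIVEN_JS_HIGH = 0.37
SC_MARGINAL_HIGH = 0.53


def solve_sc_high_given_js_low(
    sc_marginal: float = SC_MARGINAL_HIGH,
    p_sc_high_given_js_high: float = P_SC_HIGH_GIVEN_JS_HIGH,
    p_js_high: float = P_JS_HIGH,
) -> float:
    """Back out P(SC=high | JS=low) from the safety-climate marginal."""
    return (sc_marginal - p_js_high * p_sc_high_given_js_high) / (1.0 - p_js_high)


def core_network(
    p_js_high: float = P_JS_HIGH,
    p_sc_high_given_js_high: float = P_SC_HIGH_GIVEN_JS_HIGH,
    p_sc_high_given_js_low: float | None = None,
    accident_cpt_yes: dict[tuple[str, str], float] | None = None,
) -> BayesianNetwork:
    """The calibrated three-node network (JS → SC, JS → acc, SC → acc)."""
    if p_sc_high_given_js_low is None:
        p_sc_high_given_js_low = solve_sc_high_given_js_low(
            p_sc_high_given_js_high=p_sc_high_given_js_high, p_js_high=p_js_high
        )
    cpt = dict(ACCIDENT_CPT_YES if accident_cpt_yes is None else accident_cpt_yes)
    nodes = [
        NodeSpec(JOB_STRESS, LOW_HIGH),
        NodeSpec(SAFETY_CLIMATE, LOW_HIGH, (JOB_STRESS,)),
        NodeSpec(ACCIDENT, ACCIDENT_STATES, (SAFETY_CLIMATE, JOB_STRESS)),
    ]
    cpts = [
        ConditionalProbabilityTable(JOB_STRESS, (), [[1 - p_js_high, p_js_high]]),
        ConditionalProbabilityTable(
            SAFETY_CLIMATE,
            (JOB_STRESS,),
            [
                [1 - p_sc_high_given_js_low, p_sc_high_given_js_low],
                [1 - p_sc_high_given_js_high, p_sc_high_given_js_high],
            ],
        ),
        # rows: last parent (job_stress) varies fastest
        ConditionalProbabilityTable(
            ACCIDENT,
            (SAFETY_CLIMATE, JOB_STRESS),
            [
                [cpt[("low", "low")], 1 - cpt[("low", "low")]],
                [cpt[("low", "high")], 1 - cpt[("low", "high")]],
                [cpt[("high", "low")], 1 - cpt[("high", "low")]],
                [cpt[("high", "high")], 1 - cpt[("high", "high")]],
            ],
        ),
    ]
    return BayesianNetwork(nodes, cpts)


def full_structure(scale_count: int = 16, dim_count: int = 7) -> list[NodeSpec]:
    """Node specs of the full two-layer structure (no parameters).

    scales → job stress; job stress → dimensions; dimensions → safety
    climate; job stress, safety climate → accident.
    """
    scales = STRESS_SCALES[:scale_count]
    dims = CLIMATE_DIMENSIONS[:dim_count]
    specs = [NodeSpec(s, LOW_HIGH) for s in scales]
    specs.append(NodeSpec(JOB_STRESS, LOW_HIGH, scales))
    specs.extend(NodeSpec(d, LOW_HIGH, (JOB_STRESS,)) for d in dims)
    specs.append(NodeSpec(SAFETY_CLIMATE, LOW_HIGH, dims))
    specs.append(NodeSpec(ACCIDENT, ACCIDENT_STATES, (SAFETY_CLIMATE, JOB_STRESS)))
    return specs


def candidate_edges(scale_count: int = 16, dim_count: int = 7) -> list[tuple[str, str]]:
    """The (parent, child) pairs submitted to expert elicitation."""
    pairs = [(s, JOB_STRESS) for s in STRESS_SCALES[:scale_count]]
    pairs += [(JOB_STRESS, d) for d in CLIMATE_DIMENSIONS[:dim_count]]
    pairs += [(d, SAFETY_CLIMATE) for d in CLIMATE_DIMENSIONS[:dim_count]]
    pairs += [(JOB_STRESS, ACCIDENT), (SAFETY_CLIMATE, ACCIDENT)]
    return pairs


def default_expert_opinions(
    n_experts: int = 5,
    forward_mass: float = 0.8,
    scale_count: int = 16,
    dim_count: int = 7,
) -> pd.DataFrame:
    """A deterministic demonstration panel of expert edge opinions.

    Each of ``n_experts`` experts puts ``forward_mass`` on the forward
    hypothesis of every canonical candidate edge and the remainder on full
    ignorance (the whole frame).  Combining these opinions reproduces the
    canonical structure; the table doubles as a format example for the
    expert-opinion interface (columns expert, node_a, node_b, subset, mass).
    """
    rows = []
    for e in range(1, n_experts + 1):
        for a, b in candidate_edges(scale_count, dim_count):
            rows.append({"expert": f"expert{e}", "node_a": a, "node_b": b,
                         "subset": "F", "mass": forward_mass})
            rows.append({"expert": f"expert{e}", "node_a": a, "node_b": b,
                         "subset": "FBN", "mass": round(1.0 - forward_mass, 12)})
    return pd.DataFrame(rows)
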