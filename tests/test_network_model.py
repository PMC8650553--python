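"""Exact inference on discrete networks, checked against enumeration."""

import json

import numpy as np
import pytest
from helpers import brute_posterior, random_network

from safebn.network import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    IncompleteAssignmentError,
    InconsistentEvidenceError,
    NetworkFormatError,
    NodeSpec,
    deserialize_network,
    joint_probability,
    log_joint_probability,
    marginal,
    posterior,
    serialize_network,
    validate_network,
)


class TestValidation:
    def test_well_formed_core_network(self, core_net):
        assert validate_network(core_net) == []

    def test_two_cycle_reported(self):
        nodes = [
            NodeSpec("a", ("s0", "s1"), ("b",)),
            NodeSpec("b", ("s0", "s1"), ("a",)),
        ]
        cpts = [
            ConditionalProbabilityTable("a", ("b",), [[0.5, 0.5], [0.5, 0.5]]),
            ConditionalProbabilityTable("b", ("a",), [[0.5, 0.5], [0.5, 0.5]]),
        ]
        problems = validate_network(BayesianNetwork(nodes, cpts))
        assert any("cycle" in p for p in problems)

    def test_unnormalized_row_reported(self):
        net = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1"))],
            [ConditionalProbabilityTable("a", (), [[0.5, 0.4]])],
        )
        assert any("not normalized" in p for p in validate_network(net))

    def test_incomplete_cpt_and_self_parent(self):
        net = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1")), NodeSpec("b", ("s0", "s1"), ("a",))],
            [
                ConditionalProbabilityTable("a", (), [[0.5, 0.5]]),
                ConditionalProbabilityTable("b", ("a",), [[0.5, 0.5]]),  # one row short
            ],
        )
        assert any("rows" in p for p in validate_network(net))
        net2 = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1"), ("a",))],
            [ConditionalProbabilityTable("a", ("a",), [[0.5, 0.5], [0.5, 0.5]])],
        )
        assert any("itself" in p for p in validate_network(net2))


class TestJointProbability:
    def test_chain_rule_product(self, core_net):
        p = joint_probability(
            core_net,
            {"job_stress": "high", "safety_climate": "high", "accident": "yes"},
        )
        assert p == pytest.approx(0.5 * 0.37 * 0.95)  # = 0.17575

    def test_zero_entry_annihilates(self):
        net = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1")), NodeSpec("b", ("s0", "s1"), ("a",))],
            [
                ConditionalProbabilityTable("a", (), [[1.0, 0.0]]),
                ConditionalProbabilityTable("b", ("a",), [[0.3, 0.7], [0.5, 0.5]]),
            ],
        )
        assert joint_probability(net, {"a": "s1", "b": "s0"}) == 0.0
        assert log_joint_probability(net, {"a": "s1", "b": "s0"}) == -np.inf

    def test_single_root_identity(self):
        net = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1"))],
            [ConditionalProbabilityTable("a", (), [[1.0, 0.0]])],
        )
        assert joint_probability(net, {"a": "s0"}) == 1.0

    def test_incomplete_assignment_raises(self, core_net):
        with pytest.raises(IncompleteAssignmentError):
            joint_probability(core_net, {"job_stress": "high"})


class TestStudyQueries:
    """The calibrated network reproduces the published probabilities."""

    def test_marginals(self, core_net):
        assert marginal(core_net, "accident")["yes"] == pytest.approx(0.72, abs=0.005)
        assert marginal(core_net, "safety_climate")["high"] == pytest.approx(0.53, abs=1e-12)
        # root marginal equals its prior row
        assert marginal(core_net, "job_stress").distribution == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize(
        "node, evidence, state, expected_pct",
        [
            ("accident", {"job_stress": "high"}, "yes", 94),
            ("accident", {"job_stress": "high", "safety_climate": "low"}, "yes", 93),
            ("job_stress", {"accident": "yes"}, "high", 65),
            ("safety_climate", {"accident": "yes"}, "high", 40),
            ("safety_climate", {"job_stress": "high"}, "high", 37),
        ],
    )
    def test_posterior_shifts_round_to_published_percents(
        self, core_net, node, evidence, state, expected_pct
    ):
        p = posterior(core_net, node, evidence)[state]
        assert round(100 * p) == expected_pct

    def test_accident_given_low_safety_climate(self, core_net):
        # 0.434 / 0.47 from the printed CPT; the publication's rounded 93%
        # is ~0.7 points above what its own printed inputs imply.
        p = posterior(core_net, "accident", {"safety_climate": "low"})["yes"]
        assert p == pytest.approx(0.92340425, abs=1e-8)

    def test_law_of_total_probability(self, core_net):
        total = sum(
            posterior(core_net, "accident", {"job_stress": s})["yes"]
            * marginal(core_net, "job_stress")[s]
            for s in ("low", "high")
        )
        assert total == pytest.approx(marginal(core_net, "accident")["yes"], abs=1e-12)


class TestPosteriorMechanics:
    def test_evidence_node_returns_indicator(self, core_net):
        r = posterior(core_net, "job_stress", {"job_stress": "high"})
        assert r.as_dict() == {"low": 0.0, "high": 1.0}

    def test_zero_probability_evidence_raises(self):
        net = BayesianNetwork(
            [NodeSpec("a", ("s0", "s1")), NodeSpec("b", ("s0", "s1"), ("a",))],
            [
                ConditionalProbabilityTable("a", (), [[1.0, 0.0]]),
                ConditionalProbabilityTable("b", ("a",), [[0.3, 0.7], [0.5, 0.5]]),
            ],
        )
        with pytest.raises(InconsistentEvidenceError):
            posterior(net, "b", {"a": "s1"})

    def test_unknown_node_raises(self, core_net):
        with pytest.raises(Exception, match="unknown"):
            marginal(core_net, "nonexistent")

    def test_elimination_matches_enumeration_on_random_networks(self):
        """Variable elimination ≡ brute-force enumeration, all ≤12-node nets."""
        rng = np.random.default_rng(1234)
        for trial in range(30):
            n = int(rng.integers(2, 13))
            net = random_network(rng, n)
            names = list(net.nodes)
            query = names[int(rng.integers(0, n))]
            ev_candidates = [v for v in names if v != query]
            n_ev = int(rng.integers(0, min(3, len(ev_candidates)) + 1))
            evidence = {
                v: net.nodes[v].states[int(rng.integers(0, 2))]
                for v in rng.choice(ev_candidates, size=n_ev, replace=False)
            }
            expected = brute_posterior(net, query, evidence)
            if expected.sum() == 0:
                continue  # evidence impossible under this random draw
            got = posterior(net, query, evidence).distribution
            np.testing.assert_allclose(got, expected, atol=1e-10)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)


class TestSerialization:
    def test_round_trip_identity(self, core_net):
        assert deserialize_network(serialize_network(core_net)) == core_net

    def test_missing_row_names_configuration(self, core_net):
        doc = json.loads(serialize_network(core_net))
        for entry in doc["cpts"]:
            if entry["child"] == "accident":
                entry["rows"] = entry["rows"][:3]
        with pytest.raises(NetworkFormatError, match="accident.*missing parent configuration"):
            deserialize_network(json.dumps(doc))

    def test_reordered_parents_rejected(self, core_net):
        doc = json.loads(serialize_network(core_net))
        for entry in doc["cpts"]:
            if entry["child"] == "accident":
                entry["parent_order"] = list(reversed(entry["parent_order"]))
        with pytest.raises(NetworkFormatError, match="accident"):
            deserialize_network(json.dumps(doc))

    def test_unnormalized_row_rejected(self, core_net):
        doc = json.loads(serialize_network(core_net))
        doc["cpts"][0]["rows"][0] = [0.5, 0.4]
        with pytest.raises(NetworkFormatError, match="not normalized"):
            deserialize_network(json.dumps(doc))

    def test_unknown_parent_reference_rejected(self):
        doc = {
            "nodes": [{"name": "a", "states": ["s0", "s1"], "parents": ["ghost"]}],
            "cpts": [],
        }
        with pytest.raises(NetworkFormatError, match="ghost"):
            deserialize_network(json.dumps(doc))
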