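import numpy as np
import pytest

from causalbn import (
    ArgmaxTarget,
    AssignTarget,
    QuerySyntaxError,
    StateSpace,
    CausalNetwork,
    apply_do,
    argmax_posterior,
    evaluate_query,
    parse_query,
    posterior_probability,
    read_sif,
    unparse_query,
    validate_query,
)
from causalbn.interventions import Intervention
from causalbn.learning import EMConfig, em_fit
from causalbn.synthetic import forward_sample, make_sprinkler

TABLE1_QUERIES = [
    "? argmax(AKT)",
    "? argmax(AKT) ! do ERK = 2",
    "? argmax(AKT) ! do ERK = 0",
    "? argmax(PKA)",
    "? argmax(PKA) ! do ERK = 2",
    "? argmax(PKA) ! do ERK = 0",
    "? argmax(PKA) | ERK = 2",
    "? argmax(PKA) | ERK = 0",
]


@pytest.fixture(scope="module")
def sachs_network(fixtures_dir):
    topology = read_sif((fixtures_dir / "sachs_consensus.sif").read_text())
    states = StateSpace.from_cards({n: 3 for n in topology.nodes})
    return CausalNetwork(topology=topology, states=states, cpts={})


# conftest fixture is function-scoped; re-declare at module scope here
@pytest.fixture(scope="module")
def fixtures_dir():
    from pathlib import Path

    return Path(__file__).parent.parent / "src" / "causalbn" / "fixtures"


class TestParse:
    def test_argmax_with_do(self):
        q = parse_query("? argmax(AKT) ! do ERK = 2")
        assert q.targets == (ArgmaxTarget("AKT"),)
        assert q.evidence == ()
        assert q.interventions[0].kind == "do_assignment"
        assert (q.interventions[0].node, q.interventions[0].state) == ("ERK", "2")

    def test_argmax_with_evidence(self):
        q = parse_query("? argmax(PKA) | ERK = 0")
        assert q.targets == (ArgmaxTarget("PKA"),)
        assert q.evidence == (("ERK", "0"),)
        assert q.interventions == ()

    def test_assignment_targets_and_edges(self):
        q = parse_query("? A = 1 B = 0 | C = 2 ! + A B - C A")
        assert q.targets == (AssignTarget("A", "1"), AssignTarget("B", "0"))
        assert q.interventions == (
            Intervention.add_edge("A", "B"),
            Intervention.remove_edge("C", "A"),
        )

    def test_no_target_is_syntax_error(self):
        with pytest.raises(QuerySyntaxError):
            parse_query("? ! do A = 1")

    def test_missing_question_mark(self):
        with pytest.raises(QuerySyntaxError):
            parse_query("argmax(A)")

    def test_error_carries_position(self):
        with pytest.raises(QuerySyntaxError) as exc:
            parse_query("? argmax(A) ! boom")
        assert exc.value.position == 14

    def test_duplicate_do_target_rejected(self):
        with pytest.raises(QuerySyntaxError, match="do-target"):
            parse_query("? argmax(B) ! do A = 1 do A = 0")

    def test_whitespace_insensitive(self):
        a = parse_query("?argmax(AKT)!do ERK=2")
        b = parse_query("? argmax(AKT) ! do ERK = 2")
        assert a == b


class TestUnparse:
    @pytest.mark.parametrize("text", TABLE1_QUERIES)
    def test_round_trip_is_identity_on_surface(self, text):
        assert unparse_query(parse_query(text)) == text

    def test_round_trip_on_ast(self):
        text = "? A = 1 argmax(B) | C = 0 ! do D = 2 + E F - F G"
        q = parse_query(text)
        assert parse_query(unparse_query(q)) == q


class TestValidate:
    def test_unknown_node(self, sachs_network):
        report = validate_query(parse_query("? argmax(FOO)"), sachs_network)
        assert any("unknown node 'FOO'" in r for r in report)

    def test_state_out_of_range(self, sachs_network):
        report = validate_query(
            parse_query("? argmax(AKT) ! do ERK = 7"), sachs_network
        )
        assert any("out of range" in r for r in report)

    def test_unknown_node_in_edge_removal(self, sachs_network):
        report = validate_query(
            parse_query("? argmax(AKT) ! - ERK FOO"), sachs_network
        )
        assert any("unknown node 'FOO'" in r for r in report)

    def test_cycle_creating_addition(self, sachs_network):
        report = validate_query(
            parse_query("? argmax(PKA) ! + AKT ERK + ERK PKA"), sachs_network
        )
        assert any("cycle" in r for r in report)

    @pytest.mark.parametrize("text", TABLE1_QUERIES)
    def test_table1_queries_validate(self, text, sachs_network):
        assert validate_query(parse_query(text), sachs_network) == []


class TestEvaluate:
    def test_assignment_on_single_node(self, single_binary):
        res = evaluate_query(parse_query("? A = 0"), single_binary)
        assert res.joint_probability == pytest.approx(0.75)

    def test_dispatch_matches_direct_inference(self, sprinkler):
        res = evaluate_query(parse_query("? R = 1 | W = 1"), sprinkler)
        assert res.joint_probability == pytest.approx(
            posterior_probability(sprinkler, [("R", 1)], {"W": 1})
        )
        res2 = evaluate_query(parse_query("? argmax(R) | W = 1"), sprinkler)
        assert res2.argmax[0][1:] == pytest.approx(
            argmax_posterior(sprinkler, "R", {"W": 1})
        )

    def test_argmax_probability_is_max_over_assignments(self, sprinkler):
        _, _, p_max = evaluate_query(parse_query("? argmax(S) | W = 1"), sprinkler).argmax[0]
        assignments = [
            evaluate_query(parse_query(f"? S = {s} | W = 1"), sprinkler).joint_probability
            for s in (0, 1)
        ]
        assert p_max == pytest.approx(max(assignments))

    def test_intervention_only_uses_mutilated_network(self, sprinkler):
        res = evaluate_query(parse_query("? W = 1 ! do S = 1"), sprinkler)
        assert res.joint_probability == pytest.approx(0.918, abs=1e-9)

    def test_counterfactual_dispatch(self, chain_xy):
        res = evaluate_query(parse_query("? Y = 1 | X = 0 Y = 0 ! do X = 1"), chain_xy)
        assert res.joint_probability == pytest.approx(0.9)

    def test_single_world_semantics(self, sprinkler):
        res = evaluate_query(
            parse_query("? W = 1 | R = 1 ! do S = 1"), sprinkler, worlds="single"
        )
        mutilated_cond = posterior_probability(
            apply_do(sprinkler, [("S", 1)]), [("W", 1)], {"R": 1}
        )
        assert res.joint_probability == pytest.approx(mutilated_cond)

    def test_display_labels_resolve(self):
        from causalbn import CPT, Topology

        net = CausalNetwork(
            Topology(["A"]),
            StateSpace({"A": ("low", "high")}),
            {"A": CPT("A", (), np.array([0.7, 0.3]))},
        )
        res = evaluate_query(parse_query("? A = high"), net)
        assert res.joint_probability == pytest.approx(0.3)

    def test_invalid_query_raises(self, sprinkler):
        with pytest.raises(ValueError, match="invalid query"):
            evaluate_query(parse_query("? argmax(NOPE)"), sprinkler)


def test_full_pipeline_on_learned_sprinkler():
    """Learn from complete samples, then query through the language."""
    truth = make_sprinkler()
    data = forward_sample(truth, 4000, seed=77).astype(float)
    fit = em_fit(truth, data, EMConfig(seed=78))
    res = evaluate_query(parse_query("? argmax(R) | W = 1"), fit.network)
    node, state, p = res.argmax[0]
    assert (node, state) == ("R", 0)
    assert p == pytest.approx(0.6423, abs=0.05)
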