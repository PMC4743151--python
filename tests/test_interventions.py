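import numpy as np
import pytest

from causalbn import (
    Intervention,
    apply_do,
    apply_edge_intervention,
    build_twin_network,
    counterfactual_query,
    is_ancestor,
    ml_counts,
    posterior_probability,
    variable_elimination,
)
from causalbn.synthetic import forward_sample, make_random_network

from oracles import enum_probability


class TestApplyDo:
    def test_do_differs_from_conditioning(self, sprinkler):
        do_p = posterior_probability(apply_do(sprinkler, [("S", 1)]), [("W", 1)])
        cond_p = posterior_probability(sprinkler, [("W", 1)], {"S": 1})
        assert do_p == pytest.approx(0.918, abs=1e-9)
        assert cond_p == pytest.approx(0.9006, abs=5e-5)
        assert abs(do_p - cond_p) > 1e-3

    def test_matches_enumeration_on_mutilated_network(self, sprinkler):
        mutilated = apply_do(sprinkler, [("S", 1)])
        assert posterior_probability(mutilated, [("W", 1)]) == pytest.approx(
            enum_probability(mutilated, [("W", 1)])
        )

    def test_do_on_childless_node_changes_nothing_else(self, sprinkler):
        mutilated = apply_do(sprinkler, [("W", 0)])
        for node in ("R", "S"):
            np.testing.assert_allclose(
                variable_elimination(mutilated, [node]).values,
                variable_elimination(sprinkler, [node]).values,
                atol=1e-12,
            )

    def test_mutilation_locality(self, sprinkler):
        mutilated = apply_do(sprinkler, [("S", 1)])
        assert mutilated.parents("S") == ()
        np.testing.assert_array_equal(mutilated.cpt("S").table, [0.0, 1.0])
        for node in ("R", "W"):
            np.testing.assert_array_equal(
                mutilated.cpt(node).table, sprinkler.cpt(node).table
            )

    def test_state_out_of_range(self, sprinkler):
        with pytest.raises(ValueError, match="out of range"):
            apply_do(sprinkler, [("S", 5)])


class TestEdgeInterventions:
    def test_remove_only_edge_gives_marginal_frequency(self, chain_xy):
        data = forward_sample(chain_xy, 500, seed=2).astype(float)
        net = ml_counts(chain_xy, data)
        cut = apply_edge_intervention(net, "remove", "X", "Y")
        assert cut.parents("Y") == ()
        freq = data.loc["Y"].mean()
        np.testing.assert_allclose(cut.cpt("Y").table, [1 - freq, freq])

    def test_add_then_remove_recovers_network(self, sprinkler):
        data = forward_sample(sprinkler, 400, seed=8).astype(float)
        net = ml_counts(sprinkler, data)
        # R -> S exists; S -> W exists; add a fresh arc R-independent
        added = apply_edge_intervention(net, "remove", "R", "W")
        back = apply_edge_intervention(added, "add", "R", "W")
        for n in net.nodes:
            np.testing.assert_allclose(
                back.cpt(n).table, net.cpt(n).table, atol=1e-12
            )

    def test_add_cycle_rejected(self, chain_xy):
        with pytest.raises(ValueError):
            apply_edge_intervention(chain_xy, "add", "Y", "X")

    def test_remove_absent_edge_rejected(self, chain_xy):
        with pytest.raises(ValueError, match="not present"):
            apply_edge_intervention(chain_xy, "remove", "Y", "X")

    def test_edge_surgery_without_data(self, chain_xy):
        # no training data retained: removal averages the CPT over the
        # removed parent's marginal; addition replicates across the new axis
        assert chain_xy.training_data is None
        cut = apply_edge_intervention(chain_xy, "remove", "X", "Y")
        np.testing.assert_allclose(cut.cpt("Y").table, [0.5, 0.5])
        readded = apply_edge_intervention(cut, "add", "X", "Y")
        np.testing.assert_allclose(readded.cpt("Y").table, [[0.5, 0.5], [0.5, 0.5]])


class TestTwinNetwork:
    def test_chain_do_copies_everything_downstream(self, chain_xy):
        twin = build_twin_network(chain_xy, [Intervention.do("X", 1)])
        assert twin.counterfactual("X") == "X*"
        assert twin.counterfactual("Y") == "Y*"
        np.testing.assert_array_equal(twin.network.cpt("X*").table, [0.0, 1.0])
        assert twin.network.cpt("Y*").parents == ("X*",)

    def test_collider_shares_non_descendants(self):
        from causalbn import CPT, CausalNetwork, StateSpace, Topology

        net = CausalNetwork(
            Topology(["A", "B", "C"], [("A", "C"), ("B", "C")]),
            StateSpace.from_cards({"A": 2, "B": 2, "C": 2}),
            {
                "A": CPT("A", (), np.array([0.3, 0.7])),
                "B": CPT("B", (), np.array([0.6, 0.4])),
                "C": CPT("C", ("A", "B"), np.full((2, 2, 2), 0.5)),
            },
        )
        twin = build_twin_network(net, [Intervention.do("C", 1)])
        assert twin.counterfactual("A") == "A"
        assert twin.counterfactual("B") == "B"
        assert twin.counterfactual("C") == "C*"

    def test_no_interventions_identity(self, chain_xy):
        twin = build_twin_network(chain_xy, [])
        assert twin.network.topology == chain_xy.topology
        assert all(twin.counterfactual(n) == n for n in chain_xy.nodes)


class TestCounterfactuals:
    def test_chain_counterfactual(self, chain_xy):
        # observed X=0, Y=0; had X been 1, Y* is redrawn from P(Y|X=1)
        f = counterfactual_query(
            chain_xy, ["Y"], {"X": 0, "Y": 0}, [Intervention.do("X", 1)]
        )
        assert f.values[1] == pytest.approx(0.9)

    def test_empty_evidence_equals_interventional(self, sprinkler):
        cf = counterfactual_query(sprinkler, ["W"], {}, [Intervention.do("S", 1)])
        iv = variable_elimination(apply_do(sprinkler, [("S", 1)]), ["W"])
        np.testing.assert_allclose(cf.values, iv.values, atol=1e-12)

    def test_empty_interventions_equals_conditional(self, sprinkler):
        cf = counterfactual_query(sprinkler, ["R"], {"W": 1}, [])
        cond = variable_elimination(sprinkler, ["R"], {"W": 1})
        np.testing.assert_allclose(cf.values, cond.values, atol=1e-12)

    def test_twin_network_is_acyclic_and_valid(self, sprinkler):
        from causalbn import validate_network

        twin = build_twin_network(sprinkler, [Intervention.do("R", 1)])
        assert validate_network(twin.network) == []


@pytest.mark.parametrize("seed", range(12))
def test_intervention_invariance(seed):
    """P(T | do(X=x)) = P(T) whenever X is not an ancestor of T."""
    net = make_random_network(6, seed=seed + 500)
    nodes = list(net.topology.nodes)
    for x in nodes:
        for t in nodes:
            if t == x or is_ancestor(net.topology, x, t):
                continue
            base = variable_elimination(net, [t]).values
            for state in range(net.card(x)):
                mutilated = apply_do(net, [(x, state)])
                np.testing.assert_allclose(
                    variable_elimination(mutilated, [t]).values, base, atol=1e-9
                )
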