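import numpy as np
import pandas as pd
import pytest

from causalbn import (
    CPT,
    CausalNetwork,
    EMConfig,
    StateSpace,
    Topology,
    em_fit,
    init_cpts,
    log_likelihood,
    ml_counts,
    validate_network,
)
from causalbn.learning import INIT_SCHEMES
from causalbn.synthetic import forward_sample, inject_missing, make_sprinkler

from oracles import loglik_by_enumeration


def frame(rows: dict) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"s{i}" for i in range(n)]).astype(float)


@pytest.fixture
def chain_ab() -> CausalNetwork:
    return CausalNetwork(
        topology=Topology(["A", "B"], [("A", "B")]),
        states=StateSpace.from_cards({"A": 2, "B": 2}),
        cpts={
            "A": CPT("A", (), np.array([0.5, 0.5])),
            "B": CPT("B", ("A",), np.full((2, 2), 0.5)),
        },
    )


class TestMlCounts:
    def test_root_frequency(self, single_binary):
        fitted = ml_counts(single_binary, frame({"A": [1, 1, 0, 1]}))
        np.testing.assert_allclose(fitted.cpt("A").table, [0.25, 0.75])

    def test_unseen_parent_config_uniform(self, chain_ab):
        # A is always 0, so the A=1 row of B's CPT is never observed
        fitted = ml_counts(chain_ab, frame({"A": [0, 0], "B": [1, 0]}))
        np.testing.assert_allclose(fitted.cpt("B").table[1], [0.5, 0.5])

    def test_chain_conditionals_match_hand_counts(self, chain_ab):
        data = frame({"A": [0, 0, 1, 1], "B": [0, 1, 1, 1]})
        fitted = ml_counts(chain_ab, data)
        np.testing.assert_allclose(fitted.cpt("A").table, [0.5, 0.5])
        np.testing.assert_allclose(fitted.cpt("B").table, [[0.5, 0.5], [0.0, 1.0]])
        assert validate_network(fitted) == []

    def test_missing_entries_rejected(self, single_binary):
        with pytest.raises(ValueError, match="complete data"):
            ml_counts(single_binary, frame({"A": [1, np.nan]}))

    def test_variable_absent_from_data(self, chain_ab):
        with pytest.raises(ValueError, match="absent"):
            ml_counts(chain_ab, frame({"A": [0, 1]}))


class TestLogLikelihood:
    def test_complete_samples_chain_rule(self, sprinkler):
        data = forward_sample(sprinkler, 40, seed=3).astype(float)
        assert log_likelihood(sprinkler, data) == pytest.approx(
            loglik_by_enumeration(sprinkler, data)
        )

    def test_fully_missing_sample_contributes_zero(self, single_binary):
        base = frame({"A": [1, 0]})
        with_blank = frame({"A": [1, 0, np.nan]})
        assert log_likelihood(single_binary, base) == pytest.approx(
            log_likelihood(single_binary, with_blank)
        )

    def test_two_fair_coin_samples(self):
        net = CausalNetwork(
            Topology(["A"]), StateSpace.from_cards({"A": 2}),
            {"A": CPT("A", (), np.array([0.5, 0.5]))},
        )
        assert log_likelihood(net, frame({"A": [1, 0]})) == pytest.approx(
            2 * np.log(0.5)
        )

    def test_missing_marginalised_matches_enumeration(self, sprinkler):
        data = inject_missing(forward_sample(sprinkler, 40, seed=5), 0.3, seed=6)
        assert log_likelihood(sprinkler, data) == pytest.approx(
            loglik_by_enumeration(sprinkler, data)
        )

    def test_impossible_sample_is_minus_inf(self, sprinkler):
        # P(W=1 | R=0, S=0) = 0 in the fixture
        data = frame({"R": [0.0], "S": [0.0], "W": [1.0]})
        assert log_likelihood(sprinkler, data) == float("-inf")


class TestInitSchemes:
    def test_uniform(self, chain_ab):
        net = init_cpts(chain_ab, "uniform")
        np.testing.assert_allclose(net.cpt("B").table, 0.5)

    def test_random_reproducible(self, chain_ab):
        a = init_cpts(chain_ab, "random", seed=9)
        b = init_cpts(chain_ab, "random", seed=9)
        np.testing.assert_array_equal(a.cpt("B").table, b.cpt("B").table)
        c = init_cpts(chain_ab, "random", seed=10)
        assert not np.array_equal(a.cpt("B").table, c.cpt("B").table)

    def test_complete_case_equals_ml_on_complete_data(self, chain_ab):
        data = frame({"A": [0, 1, 1], "B": [1, 1, 0]})
        a = init_cpts(chain_ab, "complete_case", data=data)
        b = ml_counts(chain_ab, data)
        for n in ("A", "B"):
            np.testing.assert_allclose(a.cpt(n).table, b.cpt(n).table)

    def test_unknown_scheme_rejected(self, chain_ab):
        with pytest.raises(ValueError, match="unknown initialisation"):
            init_cpts(chain_ab, "magic")


class TestEmFit:
    def test_complete_data_degenerates_to_ml_counts(self, sprinkler):
        data = forward_sample(sprinkler, 300, seed=12).astype(float)
        expected = ml_counts(sprinkler, data)
        for scheme in INIT_SCHEMES:
            fit = em_fit(
                sprinkler, data,
                EMConfig(restarts=1, schemes=(scheme,), seed=4),
            )
            for n in sprinkler.nodes:
                np.testing.assert_allclose(
                    fit.network.cpt(n).table, expected.cpt(n).table, atol=1e-12
                )

    def test_missing_data_fixed_point(self, em_missing_data):
        # p = (2 + p) / 4 has the unique fixed point p = 2/3
        net = CausalNetwork(
            Topology(["A"]), StateSpace.from_cards({"A": 2}),
            {"A": CPT("A", (), np.array([0.5, 0.5]))},
        )
        fit = em_fit(net, em_missing_data, EMConfig(tol=1e-12, max_iter=500))
        assert fit.network.cpt("A").table[1] == pytest.approx(2 / 3, abs=1e-6)

    def test_monotone_log_likelihood(self, sprinkler):
        data = inject_missing(forward_sample(sprinkler, 400, seed=21), 0.2, seed=22)
        fit = em_fit(sprinkler, data, EMConfig(seed=23))
        for history in fit.ll_history:
            assert (np.diff(history) > -1e-9).all()

    def test_winner_has_best_log_likelihood(self, sprinkler):
        data = inject_missing(forward_sample(sprinkler, 200, seed=31), 0.3, seed=32)
        fit = em_fit(sprinkler, data, EMConfig(seed=33))
        finals = [h[-1] for h in fit.ll_history]
        assert fit.log_likelihood == pytest.approx(max(finals))
        assert validate_network(fit.network) == []

    def test_parameter_recovery_with_missing_data(self):
        truth = make_sprinkler()
        data = inject_missing(forward_sample(truth, 20000, seed=41), 0.2, seed=42)
        fit = em_fit(truth, data, EMConfig(seed=43))
        for n in truth.nodes:
            np.testing.assert_allclose(
                fit.network.cpt(n).table, truth.cpt(n).table, atol=0.03
            )

    def test_empty_data_rejected(self, single_binary):
        with pytest.raises(ValueError, match="empty data"):
            em_fit(single_binary, pd.DataFrame(index=["A"]))

    def test_unknown_scheme_in_config_rejected(self):
        with pytest.raises(ValueError, match="unknown initialisation"):
            EMConfig(schemes=("magic",))
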