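"""Decision analytics: frontier, ICERs, NMB, CEAC, EVPI."""

from __future__ import annotations

import numpy as np
import pytest

from alarmcea import ceac, compute_frontier, evpi, icer, mean_outcomes, nmb, population_evpi
from alarmcea.cea import DOMINATED, EXT_DOMINATED, FRONTIER

from _oracles import frontier_choice_by_icer, frontier_oracle
from _published_tables import BASE_CASE, BASE_CASE_INCREMENTS
from conftest import make_psa


class TestMeans:
    def test_identical_rows_and_toy_means(self):
        psa = make_psa([[1.0, 2.0], [3.0, 2.0]], [[10.0, 5.0], [20.0, 5.0]])
        means = mean_outcomes(psa)
        assert list(means["mean_qalys"]) == [2.0, 2.0]
        assert list(means["mean_cost"]) == [15.0, 5.0]

    def test_means_match_streaming_sum_oracle(self):
        rng = np.random.default_rng(8)
        q = rng.normal(25.0, 0.01, size=(5000, 7))
        c = rng.gamma(2.0, 1e4, size=(5000, 7))
        means = mean_outcomes(make_psa(q, c))
        # independent streaming (Kahan-style running) summation
        acc_q = np.zeros(7)
        acc_c = np.zeros(7)
        for i in range(5000):
            acc_q += q[i]
            acc_c += c[i]
        assert np.allclose(means["mean_qalys"], acc_q / 5000, rtol=1e-9)
        assert np.allclose(means["mean_cost"], acc_c / 5000, rtol=1e-9)


class TestIcer:
    def test_worked_values(self):
        assert icer(777.0, 0.023) == pytest.approx(33782.608695652172)
        assert icer(0.0, 0.5) == 0.0
        assert icer(-10.0, 0.5) == -20.0  # negative: a dominance situation

    def test_zero_qaly_increment_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icer(100.0, 0.0)


class TestFrontier:
    def test_published_base_case_frontier(self):
        labels, qalys, costs = zip(*[(l, q, c) for l, q, c in BASE_CASE])
        result = compute_frontier(qalys, costs, labels)
        assert result.n_excluded == 4
        assert result.frontier_labels == ("UC", "E+FE", "E+FE+F+HI")
        status = dict(zip(labels, result.status))
        assert status["E"] == EXT_DOMINATED
        assert {status[s] for s in ("E+FE+HI", "E+FE+F", "E+HI")} == {DOMINATED}
        table = result.table().set_index("strategy")
        for label, dq, dc in BASE_CASE_INCREMENTS:
            assert table.loc[label, "incremental_qalys"] == pytest.approx(dq, abs=1e-8)
            assert table.loc[label, "incremental_cost"] == pytest.approx(dc, abs=1e-9)

    def test_single_strategy_is_its_own_frontier(self):
        result = compute_frontier([1.0], [10.0], ["only"])
        assert result.status == (FRONTIER,)
        assert np.isnan(result.table()["icer"].iloc[0])

    def test_matches_brute_force_oracle_on_random_instances(self):
        """1,000 random instances of up to 8 strategies classify identically
        to exhaustive pairwise/segment enumeration."""
        rng = np.random.default_rng(314)
        for _ in range(1000):
            n = rng.integers(2, 9)
            qalys = rng.normal(25.0, 0.02, n)
            costs = rng.gamma(3.0, 7000.0, n)
            result = compute_frontier(qalys, costs)
            assert list(result.status) == frontier_oracle(qalys, costs)

    def test_icers_strictly_increase_along_frontier(self):
        rng = np.random.default_rng(2718)
        for _ in range(200):
            qalys = rng.normal(0.0, 1.0, 7)
            costs = rng.normal(0.0, 1.0, 7)
            result = compute_frontier(qalys, costs)
            chain = result.frontier_indices
            icers = [
                (costs[b] - costs[a]) / (qalys[b] - qalys[a])
                for a, b in zip(chain[:-1], chain[1:])
            ]
            assert all(x < y for x, y in zip(icers, icers[1:]))

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(99)
        qalys = rng.normal(25.0, 0.05, 7)
        costs = rng.gamma(3.0, 5000.0, 7)
        base = compute_frontier(qalys, costs)
        scaled = compute_frontier(qalys * 100000.0, costs * 100000.0)
        assert base.status == scaled.status
        assert base.frontier_indices == scaled.frontier_indices

    def test_tie_handling_is_deterministic(self):
        # equal effect: cheaper wins; equal-equal collapses to the earlier index
        result = compute_frontier([1.0, 1.0, 1.0], [5.0, 4.0, 4.0])
        assert result.status == (DOMINATED, FRONTIER, DOMINATED)


class TestNmbCeac:
    def test_nmb_identities(self):
        psa = make_psa([[1.0, 2.0]], [[30000.0, 70000.0]])
        assert np.allclose(nmb(psa, 0.0), [[-30000.0, -70000.0]])
        assert nmb(psa, 30000.0)[0, 0] == pytest.approx(0.0)

    def test_single_draw_gives_indicator(self):
        psa = make_psa([[1.0, 2.0, 0.5]], [[10.0, 10.0, 0.0]])
        result = ceac(psa, [20.0])
        assert list(result.probabilities[0]) == [0.0, 1.0, 0.0]

    def test_probabilities_sum_to_one_per_threshold(self, small_inputs):
        from alarmcea import Settings, run_psa

        psa = run_psa(
            small_inputs.table, small_inputs.posterior, small_inputs.life_table,
            small_inputs.utility_norms, Settings(n_draws=64, seed=11),
        )
        result = ceac(psa, np.arange(0.0, 100001.0, 5000.0))
        assert np.allclose(result.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(result.probabilities >= 0.0)

    def test_hand_counted_probability(self):
        """Strategy A beats B in exactly 3 of 10 draws at the threshold."""
        qalys = np.ones((10, 2))
        costs = np.full((10, 2), 100.0)
        costs[:3, 0] = 50.0  # A cheaper (higher NMB) in 3 draws
        costs[3:, 0] = 150.0
        result = ceac(make_psa(qalys, costs), [30000.0])
        assert result.probabilities[0, 0] == pytest.approx(0.3)
        assert result.probabilities[0, 1] == pytest.approx(0.7)

    def test_nmb_ties_awarded_to_cheaper_strategy(self):
        qalys = np.array([[1.0, 2.0]])
        costs = np.array([[0.0, 30000.0]])  # equal NMB at 30k
        result = ceac(make_psa(qalys, costs), [30000.0])
        assert list(result.probabilities[0]) == [1.0, 0.0]

    def test_winner_agrees_with_icer_rule_on_frontier(self):
        """For deterministic draws, the NMB-maximal strategy equals the
        frontier member selected by walking the ICER chain."""
        rng = np.random.default_rng(555)
        for _ in range(300):
            n = int(rng.integers(2, 8))
            qalys = rng.normal(25.0, 0.05, n)
            costs = rng.gamma(3.0, 5000.0, n)
            lam = float(rng.uniform(0.0, 2e5))
            frontier = compute_frontier(qalys, costs)
            choice = frontier_choice_by_icer(frontier, lam)
            result = ceac(make_psa(qalys[None, :], costs[None, :]), [lam])
            winner = int(result.probabilities[0].argmax())
            assert lam * qalys[winner] - costs[winner] == pytest.approx(
                lam * qalys[choice] - costs[choice], abs=1e-6
            )


class TestEvpi:
    def test_degenerate_psa_has_no_information_value(self):
        psa = make_psa(np.ones((50, 3)), np.tile([10.0, 20.0, 30.0], (50, 1)))
        assert evpi(psa, 30000.0).per_decision == 0.0

    def test_two_draw_textbook_example(self):
        # NMB matrix rows (10,0) and (0,10): E[max]=10, max E=5 -> EVPI 5
        psa = make_psa(np.zeros((2, 2)), [[-10.0, 0.0], [0.0, -10.0]])
        assert evpi(psa, 0.0).per_decision == pytest.approx(5.0)

    def test_matches_per_draw_argmax_oracle(self):
        rng = np.random.default_rng(17)
        q = rng.normal(25.0, 0.1, (400, 5))
        c = rng.gamma(2.0, 1e4, (400, 5))
        psa = make_psa(q, c)
        lam = 30000.0
        benefit = lam * q - c
        oracle = np.mean([row.max() for row in benefit]) - max(benefit.mean(axis=0))
        assert evpi(psa, lam).per_decision == pytest.approx(oracle, abs=1e-9)
        assert evpi(psa, lam).per_decision >= 0.0

    def test_nonnegative_across_random_psas(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            psa = make_psa(rng.normal(size=(30, 4)), rng.normal(size=(30, 4)))
            assert evpi(psa, float(rng.uniform(0, 1e5))).per_decision >= 0.0

    def test_population_evpi_closed_forms(self):
        assert population_evpi(2.0, 1000.0, 1, 0.0) == pytest.approx(2000.0)
        assert population_evpi(0.0, 31000.0, 10, 0.035) == 0.0
        annuity = sum(1.035**-t for t in range(10))
        assert population_evpi(1.0, 31000.0, 10, 0.035) == pytest.approx(31000.0 * annuity)
        undiscounted = population_evpi(1.0, 31000.0, 10, 0.035, discounted=False)
        assert undiscounted == pytest.approx(310000.0)
        assert population_evpi(1.0, 31000.0, 10, 0.035) >= 1.0  # population >= per-decision
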