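import numpy as np
import pytest

from mgcnet.protocol import (StimulusGrid, build_grid, sdf, response_matrix,
                             target_profile, cost, decision_latency,
                             winner_census, latency_cost_correlation)


class TestGrid:
    def test_base_rate_is_10_hz(self):
        assert build_grid().rate(0) == pytest.approx(0.01)

    def test_geometric_increments(self):
        g = build_grid()
        r = g.rates()
        assert np.allclose(r[1:] / r[:-1], 1.3)

    def test_top_rate_closed_form(self):
        assert build_grid().rate(9) == pytest.approx(0.01 * 1.3 ** 9)
        assert build_grid().rate(9) == pytest.approx(0.10604, abs=1e-5)

    def test_pair_count_and_timing(self):
        g = build_grid()
        assert len(g.pairs()) == 100
        assert g.onset(1) - g.onset(0) == pytest.approx(500.0)
        assert g.total_duration == pytest.approx(250.0 + 100 * 500.0)

    def test_shuffled_order_is_seeded_permutation(self):
        g = build_grid()
        a = g.pairs(order_seed=5)
        b = g.pairs(order_seed=5)
        assert a == b
        assert sorted(a) == sorted(g.pairs())
        assert a != g.pairs()

    def test_reduced_grid_subsets(self):
        g = build_grid(indices=(0, 4, 9))
        assert g.n == 3 and len(g.pairs()) == 9

    def test_bad_durations_rejected(self):
        with pytest.raises(ValueError):
            StimulusGrid(on_ms=0.0)


class TestSDF:
    def test_empty_train_zero(self):
        assert sdf(np.array([]), 100.0) == 0.0

    def test_single_spike_at_eval_time_contributes_one(self):
        assert sdf(np.array([123.0]), 123.0) == pytest.approx(1.0)

    def test_two_spike_hand_value(self):
        """Spikes at 0 and 800 ms, σ = 400, evaluated at 400 → 2·e⁻¹."""
        val = sdf(np.array([0.0, 800.0]), 400.0, sigma=400.0)
        assert val == pytest.approx(2 * np.exp(-1.0))

    def test_translation_invariance(self):
        spikes = np.array([10.0, 55.0, 300.0])
        assert sdf(spikes, 120.0) == pytest.approx(sdf(spikes + 77.0, 197.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sdf(np.array([1.0]), 0.0, sigma=-1.0)


class TestResponseMatrix:
    def test_silent_pn_all_zero(self):
        g = build_grid(indices=(0, 1, 2))
        r = response_matrix(np.array([]), g)
        assert np.all(r.values == 0.0)

    def test_spike_at_each_midpoint_gives_at_least_one(self):
        g = build_grid(indices=(0, 1, 2))
        mids = np.array([g.onset(k) + g.on_ms / 2 for k in range(9)])
        r = response_matrix(mids, g)
        assert np.all(r.values >= 1.0)

    def test_record_beyond_protocol_rejected(self):
        g = build_grid(indices=(0, 1))
        with pytest.raises(ValueError):
            response_matrix(np.array([1e6]), g)


class TestTargetProfile:
    def test_unit_ratio_profile_symmetric(self):
        w = target_profile(1.0).weights
        assert np.allclose(w, w.T)

    def test_diagonal_weights_maximal(self):
        w = target_profile(1.0).weights
        assert np.all(np.diag(w)[:, None] >= w - 1e-12)

    def test_one_to_three_ridge_shifted_by_log13_of_3(self):
        """The 1:3 ridge sits log₁.₃3 ≈ 4.19 grid steps off the diagonal."""
        prof = target_profile(3.0)
        w = prof.weights
        for i in range(6):
            assert abs(np.argmax(w[i]) - i - np.log(3) / np.log(1.3)) < 0.5

    def test_far_off_ridge_plateau_is_single_strong_punishment(self):
        prof = target_profile(1.0, a=18.0, b=1.25, c=0.3)
        w = prof.weights
        idx = np.arange(10)
        d = np.abs(idx[None, :] - idx[:, None])
        far = w[d >= 5]
        assert np.all(far < 0)
        assert np.ptp(far) < 1e-3 * abs(far.mean())
        assert far.mean() == pytest.approx(-18.0 * 0.3, rel=1e-3)

    def test_graded_punishment_near_ridge(self):
        w = target_profile(1.0).weights
        row = w[5]
        assert row[5] > row[6] > row[7] > row[8]


class TestCost:
    def test_zero_response_zero_cost(self):
        prof = target_profile(1.0)
        assert cost(np.zeros((10, 10)), prof) == 0.0

    def test_positive_part_substitution(self):
        prof = target_profile(1.0)
        r = np.clip(prof.weights, 0.0, None)
        expected = -np.sum(np.clip(prof.weights, 0, None) ** 2)
        assert cost(r, prof) == pytest.approx(expected)

    def test_monotone_in_rewarded_cells(self):
        prof = target_profile(1.0)
        r = np.ones((10, 10))
        base = cost(r, prof)
        r2 = r.copy()
        r2[3, 3] += 1.0  # ř > 0 on the diagonal
        assert cost(r2, prof) < base

    def test_bilinear_additivity(self):
        prof = target_profile(1.0)
        rng = np.random.default_rng(0)
        r1, r2 = rng.uniform(size=(10, 10)), rng.uniform(size=(10, 10))
        assert cost(r1 + r2, prof) == pytest.approx(cost(r1, prof) + cost(r2, prof))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cost(np.zeros((3, 3)), target_profile(1.0))


class TestDecisionLatency:
    WINDOW = (1000.0, 1250.0)

    def test_regular_train_latency_is_first_spike(self):
        spikes = 1000.0 + np.arange(40.0, 251.0, 20.0)
        assert decision_latency(spikes, self.WINDOW) == pytest.approx(40.0)

    def test_no_spikes_absent(self):
        assert decision_latency(np.array([]), self.WINDOW) is None

    def test_truncated_burst_absent(self):
        """A burst that dies before the end of the presentation is omitted."""
        spikes = 1000.0 + np.array([30.0, 45.0, 60.0, 80.0])
        assert decision_latency(spikes, self.WINDOW) is None

    def test_broken_train_measured_from_stable_part(self):
        spikes = 1000.0 + np.array([10.0, 120.0, 140.0, 160.0, 180.0, 200.0, 220.0])
        assert decision_latency(spikes, self.WINDOW) == pytest.approx(120.0)

    def test_inserting_earlier_qualifying_spike_never_increases_latency(self):
        spikes = 1000.0 + np.arange(80.0, 251.0, 25.0)
        base = decision_latency(spikes, self.WINDOW)
        earlier = np.sort(np.append(spikes, 1040.0))
        assert decision_latency(earlier, self.WINDOW) <= base


class TestWinnerCensus:
    WINDOW = (0.0, 250.0)

    def _train(self, start=20.0):
        return np.arange(start, 251.0, 15.0)

    def test_single_winner(self):
        groups = {"a": np.array([]), "b": np.array([5.0, 30.0]),
                  "c": self._train()}
        assert winner_census(groups, self.WINDOW) == "c"

    def test_multiple_winners_flagged(self):
        groups = {"a": self._train(), "b": np.array([]), "c": self._train(40.0)}
        assert winner_census(groups, self.WINDOW) == "multiple"

    def test_all_silent_none(self):
        groups = {g: np.array([]) for g in "abc"}
        assert winner_census(groups, self.WINDOW) == "none"


class TestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = latency_cost_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = latency_cost_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(11)
        r, _ = latency_cost_correlation(rng.normal(size=100),
                                        rng.normal(size=100))
        assert abs(r) < 0.3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            latency_cost_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            latency_cost_correlation([1.0, 2.0], [3.0, 4.0])
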