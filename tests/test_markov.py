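"""State classification, chain estimation, hit times, and random walks."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rhythmdm as r
from rhythmdm import markov


def random_smoothed_chain(n, seed, max_count=20):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, max_count, size=(n, n))
    return r.smooth_and_normalize(counts, 0.1)


class TestClassifyDeltas:
    def test_both_increase_is_UU(self):
        states = r.classify_deltas([0.5, 0.9, 1.0], [10, 12, 13])
        assert states.tolist() == [1, 1]  # UU, UU

    def test_exact_ties_are_flat(self):
        states = r.classify_deltas([0.9, 0.9, 0.9], [12, 12, 12])
        assert states.tolist() == [5, 5]  # FF

    def test_hand_classified_sequence(self):
        # H: 0.991 -> 0.8 (down) -> 0.95 (up); SC: 10 -> 10 (flat) -> 9 (down)
        states = r.classify_deltas([0.991, 0.8, 0.95], [10, 10, 9])
        assert [markov.STATE_LABELS[s - 1] for s in states] == ["DF", "UD"]

    def test_flat_tolerance_widens_flat_band(self):
        states = r.classify_deltas(
            [1.0, 1.05, 1.2], [10, 10.5, 12], flat_tol_H=0.1, flat_tol_SC=1.0
        )
        assert states.tolist() == [5, 1]  # FF then UU

    def test_too_few_cycles_excluded(self):
        with pytest.raises(markov.InsufficientDataError):
            r.classify_deltas([1.0, 2.0], [10, 11])


class TestCountsAndSmoothing:
    def test_repeated_state_counts(self):
        counts = r.count_transitions([1, 1, 1])
        assert counts[0, 0] == 2
        assert counts.sum() == 2

    def test_single_transition(self):
        counts = r.count_transitions([1, 5])
        assert counts[0, 4] == 1
        assert counts.sum() == 1

    @given(st.lists(st.integers(1, 9), min_size=2, max_size=60))
    def test_conservation(self, seq):
        assert r.count_transitions(seq).sum() == len(seq) - 1

    def test_uniform_smoothing_of_zero_counts(self):
        P = r.smooth_and_normalize(np.zeros((9, 9)), 0.1)
        assert np.allclose(P, 1 / 9)

    def test_smoothing_formula(self):
        counts = np.zeros((9, 9))
        counts[0, 1] = 9
        P = r.smooth_and_normalize(counts, 0.1)
        assert P[0, 1] == pytest.approx(9.1 / 9.9)
        assert P[0, 0] == pytest.approx(0.1 / 9.9)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_stochastic_and_positive(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(9, 9))
        P = r.smooth_and_normalize(counts, 0.1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P > 0).all()

    def test_nonpositive_pseudo_rejected(self):
        with pytest.raises(ValueError):
            r.smooth_and_normalize(np.zeros((9, 9)), 0.0)


class TestHitTimes:
    def test_two_state_geometric_closed_form(self):
        for a in (0.5, 0.2, 0.9):
            P = np.array([[1 - a, a], [0.3, 0.7]])
            h = r.expected_hit_times(P, target=2)
            assert h[0] == pytest.approx(1 / a)
            assert h[1] == 0.0

    def test_uniform_nine_state_chain(self):
        P = np.full((9, 9), 1 / 9)
        eht = r.hit_time_matrix(P)
        off = eht[~np.eye(9, dtype=bool)]
        assert np.allclose(off, 9.0)
        assert np.allclose(np.diag(eht), 0.0)
        meht = r.mean_hit_times(eht)
        assert np.allclose(meht, 8.0)  # (8 starts x 9 + self 0) / 9
        assert np.allclose(r.mean_hit_times(eht, include_self=False), 9.0)

    def test_meht_bounded_by_max_start(self):
        P = random_smoothed_chain(9, seed=1)
        eht = r.hit_time_matrix(P)
        meht = r.mean_hit_times(eht)
        assert (meht <= eht.max(axis=0) + 1e-12).all()

    def test_all_hit_times_finite_after_smoothing(self):
        # even a deterministic cycle becomes irreducible once smoothed
        counts = np.zeros((9, 9))
        for i in range(9):
            counts[i, (i + 1) % 9] = 50
        P = r.smooth_and_normalize(counts, 0.1)
        eht = r.hit_time_matrix(P)
        assert np.isfinite(eht).all()
        assert (eht[~np.eye(9, dtype=bool)] >= 1.0).all()

    def test_monte_carlo_agreement_small(self):
        P = random_smoothed_chain(3, seed=5)
        h = r.expected_hit_times(P, target=3)
        rng = np.random.default_rng(11)
        sims = []
        for _ in range(4000):
            s, steps = 0, 0
            while True:
                s = rng.choice(3, p=P[s])
                steps += 1
                if s == 2:
                    break
            sims.append(steps)
        assert np.mean(sims) == pytest.approx(h[0], rel=0.05)


class TestMatrixEntropy:
    def test_uniform_maximum(self):
        assert r.matrix_entropy(np.full((9, 9), 1 / 9)) == pytest.approx(
            9 * np.log2(9)
        )

    def test_deterministic_rows_zero(self):
        assert r.matrix_entropy(np.eye(9)) == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_smoothing_increases_entropy(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(9, 9)).astype(float)
        smoothed = r.matrix_entropy(r.smooth_and_normalize(counts, 0.1))
        # raw normalization with zero rows replaced by uniform
        raw = counts.copy()
        zero = raw.sum(axis=1) == 0
        raw[zero] = 1.0
        raw /= raw.sum(axis=1, keepdims=True)
        assert smoothed >= r.matrix_entropy(raw) - 1e-9


class TestAggregation:
    def test_single_participant_identity(self):
        counts = np.random.default_rng(0).integers(0, 10, (9, 9))
        solo = markov.TransitionModel.from_counts(counts, 0.1)
        agg = r.aggregate_group([counts], 0.1)
        assert np.allclose(solo.P, agg.P)
        assert np.allclose(solo.MEHT, agg.MEHT)

    def test_disjoint_counts_pooled(self):
        a = np.zeros((9, 9), dtype=int)
        b = np.zeros((9, 9), dtype=int)
        a[0, 1] = 3
        b[4, 5] = 2
        agg = r.aggregate_group([a, b], 0.1)
        assert agg.counts[0, 1] == 3 and agg.counts[4, 5] == 2

    def test_pooling_order_invariant(self):
        rng = np.random.default_rng(3)
        mats = [rng.integers(0, 8, (9, 9)) for _ in range(5)]
        fwd = r.aggregate_group(mats, 0.1)
        rev = r.aggregate_group(mats[::-1], 0.1)
        assert np.allclose(fwd.P, rev.P)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            r.aggregate_group([], 0.1)

    def test_average_mode_differs_from_pooling(self):
        # pooling weights the data-rich participant; averaging does not
        a = np.zeros((9, 9), dtype=int)
        a[0, 1] = 100
        b = np.ones((9, 9), dtype=int)
        pool = r.aggregate_group([a, b], 0.1, mode="pool_counts")
        avg = r.aggregate_group([a, b], 0.1, mode="average_P")
        assert not np.allclose(pool.P, avg.P)


class TestRandomWalk:
    def test_cumulative_sum_selection_example(self):
        assert r.inverse_cdf_state([0.2, 0.4, 0.4], 0.56) == 2

    def test_boundary_closed_on_the_right(self):
        assert r.inverse_cdf_state([0.2, 0.4, 0.4], 0.2) == 1
        assert r.inverse_cdf_state([0.2, 0.4, 0.4], 0.6) == 2
        assert r.inverse_cdf_state([0.2, 0.4, 0.4], 0.61) == 3

    def test_deterministic_under_seed(self):
        P = random_smoothed_chain(9, seed=2)
        occ1, h1 = r.random_walk(P, 5000, seed=99)
        occ2, h2 = r.random_walk(P, 5000, seed=99)
        assert np.array_equal(occ1, occ2) and h1 == h2

    def test_occupancy_approaches_stationary(self):
        P = random_smoothed_chain(9, seed=4)
        pi = r.stationary_distribution(P)
        occ, _ = r.random_walk(P, 40_000, seed=123)
        assert 0.5 * np.abs(occ - pi).sum() < 0.02

    def test_walk_entropy_stabilizes(self):
        P = random_smoothed_chain(9, seed=6)
        _, h_short = r.random_walk(P, 2_000, seed=1)
        _, h_long1 = r.random_walk(P, 40_000, seed=1)
        _, h_long2 = r.random_walk(P, 40_000, seed=2)
        assert abs(h_long1 - h_long2) < abs(h_short - h_long2) + 0.05

    def test_bad_steps_rejected(self):
        with pytest.raises(ValueError):
            r.random_walk(np.full((2, 2), 0.5), 0)

    def test_stationary_is_left_fixed_point(self):
        P = random_smoothed_chain(9, seed=8)
        pi = r.stationary_distribution(P)
        assert np.allclose(pi @ P, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)
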