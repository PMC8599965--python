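"""HMM inference tests: exact-enumeration oracles for the forward-backward
and Viterbi recursions, EM closed forms, metric definitions, and state
matching."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pspdyn import hmm, synth
from pspdyn.hmm import (
    GaussianHMM,
    dice_coefficient,
    dual_regression_stage1,
    fit_hmm,
    forward_backward,
    fractional_occupancy,
    match_states,
    mean_lifetimes,
    standardize_and_concatenate,
    switching_rate,
    viterbi,
)


def random_model(K, C, rng):
    means = rng.standard_normal((K, C))
    A = rng.random((C, C))
    cov = A @ A.T / C + np.eye(C)
    P = rng.random((K, K)) + 0.5
    P /= P.sum(axis=1, keepdims=True)
    init = rng.random(K) + 0.2
    init /= init.sum()
    return GaussianHMM(means, cov, P, init)


def enumerate_paths(model, X):
    """Brute-force likelihood and best path by summing over all K^T paths."""
    K, T = model.n_states, X.shape[0]
    emit = np.array(
        [[multivariate_normal.logpdf(X[t], model.means[k], model.covariance) for k in range(K)] for t in range(T)]
    )
    total = 0.0
    best_lp, best_path = -np.inf, None
    for path in product(range(K), repeat=T):
        lp = np.log(model.initial[path[0]]) + emit[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]]) + emit[t, path[t]]
        total += np.exp(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.log(total), np.array(best_path)


class TestStandardize:
    def test_zero_variance_channel_rejected(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError):
            standardize_and_concatenate([X])

    def test_idempotent_on_standardized_input(self, rng):
        X = rng.standard_normal((100, 4))
        X = (X - X.mean(0)) / X.std(0)
        out, bounds = standardize_and_concatenate([X])
        assert np.allclose(out, X, atol=1e-10)
        assert bounds == [(0, 100)]

    def test_boundaries_partition_rows(self, rng):
        out, bounds = standardize_and_concatenate(
            [rng.standard_normal((200, 5)), rng.standard_normal((305, 5))]
        )
        assert bounds == [(0, 200), (200, 505)]
        assert out.shape == (505, 5)
        for a, b in bounds:
            assert np.allclose(out[a:b].mean(0), 0, atol=1e-10)
            assert np.allclose(out[a:b].std(0), 1, atol=1e-10)


class TestForwardBackward:
    def test_single_state_gamma_and_loglik(self, rng):
        model = random_model(1, 3, rng)
        X = rng.standard_normal((40, 3))
        post = forward_backward(model, X)
        assert np.allclose(post.gamma, 1.0)
        expected = multivariate_normal.logpdf(X, model.means[0], model.covariance).sum()
        assert post.loglik == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("K,T", [(K, T) for K in (1, 2, 3) for T in (2, 3, 4, 5, 6)])
    def test_matches_path_enumeration(self, K, T):
        """Forward likelihood and Viterbi agree with exhaustive enumeration."""
        rng = np.random.default_rng(1000 * K + T)
        model = random_model(K, 2, rng)
        X = rng.standard_normal((T, 2))
        post = forward_backward(model, X)
        ll, best = enumerate_paths(model, X)
        assert post.loglik == pytest.approx(ll, abs=1e-10)
        assert np.array_equal(post.viterbi_path, best)
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_uniform_emissions_gamma_equals_chain_marginals(self):
        """With identical state means the data are uninformative, so the
        posterior reduces to the Markov chain's marginal distributions."""
        K = 3
        P = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.3, 0.3, 0.4]])
        init = np.array([0.5, 0.25, 0.25])
        model = GaussianHMM(np.zeros((K, 2)), np.eye(2), P, init)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 2))
        post = forward_backward(model, X)
        marg = init.copy()
        for t in range(6):
            assert np.allclose(post.gamma[t], marg, atol=1e-10)
            marg = marg @ P


class TestViterbi:
    def test_single_state_constant(self, rng):
        model = random_model(1, 2, rng)
        assert np.all(viterbi(model, rng.standard_normal((30, 2))) == 0)

    def test_low_noise_recovers_generating_path(self):
        means = synth.make_state_basis(3, 6, seed=1)
        P = 0.9 * np.eye(3) + 0.05 * (1 - np.eye(3))
        X, path = synth.simulate_subject(P, means, 1e-8 * np.eye(6), 300, seed=2)
        model = GaussianHMM(means, 1e-8 * np.eye(6), P, np.full(3, 1 / 3))
        assert np.array_equal(viterbi(model, X), path)


class TestFitHMM:
    def test_single_state_closed_form(self, rng):
        X = rng.standard_normal((500, 4))
        Xs, bounds = standardize_and_concatenate([X])
        model, _ = fit_hmm(Xs, bounds, K=1, n_restarts=1, seed=0)
        assert np.allclose(model.means[0], Xs.mean(axis=0), atol=1e-8)
        expected_cov = np.cov(Xs, rowvar=False, ddof=0)
        expected_cov += 1e-6 * np.trace(expected_cov) / 4 * np.eye(4)
        assert np.allclose(model.covariance, expected_cov, atol=1e-6)

    def test_loglik_monotone_and_deterministic(self, small_cohort):
        X, bounds = standardize_and_concatenate(small_cohort.timeseries)
        m1, _ = fit_hmm(X, bounds, K=4, n_restarts=1, seed=3, max_iter=50)
        m2, _ = fit_hmm(X, bounds, K=4, n_restarts=1, seed=3, max_iter=50)
        trace = np.array(m1.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.transition, m2.transition)

    def test_two_state_transition_recovery(self):
        means = synth.make_state_basis(2, 4, seed=0)
        P = np.array([[0.9, 0.1], [0.15, 0.85]])
        X, _ = synth.simulate_subject(P, means, 0.2 * np.eye(4), 3000, seed=1)
        Xs, bounds = standardize_and_concatenate([X])
        model, _ = fit_hmm(Xs, bounds, K=2, n_restarts=2, seed=1)
        truth = GaussianHMM(means, 0.2 * np.eye(4), P, np.full(2, 0.5))
        perm, _ = match_states(truth, model, method="correlation")
        Pest = model.transition[np.ix_(perm, perm)]
        assert np.abs(Pest - P).max() < 0.05

    def test_too_short_input_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            fit_hmm(X, [(0, 30)], K=4)


class TestTemporalMetrics:
    def test_occupancy_from_hard_path(self):
        gamma = np.zeros((100, 3))
        gamma[:30, 1] = 1.0
        gamma[30:, 0] = 1.0
        fo = fractional_occupancy(gamma)
        assert fo[1] == pytest.approx(0.30)
        assert fo.sum() == pytest.approx(1.0, abs=1e-10)

    def test_occupancy_uniform(self):
        assert np.allclose(fractional_occupancy(np.full((50, 4), 0.25)), 0.25)

    def test_occupancy_conservation(self, rng):
        g = rng.random((200, 5))
        g /= g.sum(axis=1, keepdims=True)
        assert fractional_occupancy(g).sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize(
        "path,expected",
        [
            ([0, 0, 0, 0], 0.0),
            ([0, 1, 0, 1, 0], 1.0),
            ([1, 1, 2, 2, 2, 1], 0.4),
        ],
    )
    def test_switching_rate(self, path, expected):
        assert switching_rate(np.array(path)) == pytest.approx(expected)

    def test_switching_rate_needs_two_volumes(self):
        with pytest.raises(ValueError):
            switching_rate(np.array([1]))

    def test_mean_lifetimes(self):
        path = np.array([0, 0, 1, 1, 1, 0])
        lt = mean_lifetimes(path, 3)
        assert lt[0] == pytest.approx(1.5)  # runs of 2 and 1
        assert lt[1] == pytest.approx(3.0)
        assert np.isnan(lt[2])


class TestStateMatching:
    def test_self_match_is_identity(self, rng):
        model = random_model(4, 10, rng)
        perm, dice = match_states(model, model)
        assert np.array_equal(perm, np.arange(4))
        assert np.allclose(dice, 1.0)

    def test_reversed_states(self, rng):
        model = random_model(4, 10, rng)
        rev = GaussianHMM(
            model.means[::-1].copy(), model.covariance, model.transition, model.initial
        )
        perm, _ = match_states(model, rev)
        assert np.array_equal(perm, np.array([3, 2, 1, 0]))

    def test_noisy_refits_match_by_map_correlation(self):
        """Two fits of the same ground truth pair up with high map correlation."""
        spec = synth.CohortSpec(
            n_control=6, n_case=6, n_channels=8, n_timepoints=250, n_states=3, seed=8
        )
        coh = synth.simulate_cohort(spec)
        X, bounds = standardize_and_concatenate(coh.timeseries)
        m1, _ = fit_hmm(X, bounds, K=3, n_restarts=2, seed=1)
        m2, _ = fit_hmm(X, bounds, K=3, n_restarts=2, seed=99)
        perm, _ = match_states(m1, m2, method="correlation")
        corrs = [np.corrcoef(m1.means[k], m2.means[perm[k]])[0, 1] for k in range(3)]
        assert min(corrs) > 0.8


class TestDice:
    def test_identical_nonempty(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert dice_coefficient(a, a) == 1.0

    def test_disjoint(self):
        assert dice_coefficient(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_half_overlap(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([0, 1, 1, 0], dtype=bool)
        assert dice_coefficient(a, b) == 0.5

    def test_both_empty_is_zero(self):
        assert dice_coefficient(np.zeros(3, bool), np.zeros(3, bool)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros(3, bool), np.zeros(4, bool))


class TestDualRegression:
    def test_orthonormal_maps_exact_recovery(self, rng):
        maps, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        maps = maps.T  # (5, 50) orthonormal rows
        tc = rng.standard_normal((30, 5))
        data = tc @ maps
        rec = dual_regression_stage1(maps, data)
        assert np.allclose(rec, tc, atol=1e-10)

    def test_scaling_linearity(self, rng):
        maps = rng.standard_normal((4, 40))
        data = rng.standard_normal((20, 40))
        a = dual_regression_stage1(maps, data)
        b = dual_regression_stage1(2 * maps, data)
        assert np.allclose(b, a / 2, atol=1e-10)

    def test_noise_bounded_recovery(self, rng):
        maps = rng.standard_normal((4, 200))
        tc = rng.standard_normal((60, 4))
        data = tc @ maps + 0.01 * rng.standard_normal((60, 200))
        rec = dual_regression_stage1(maps, data)
        assert np.abs(rec - tc).max() < 0.05

    def test_rank_deficient_maps_rejected(self, rng):
        maps = np.vstack([np.ones((2, 30)), rng.standard_normal((1, 30))])
        with pytest.raises(ValueError):
            dual_regression_stage1(maps, rng.standard_normal((10, 30)))
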