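"""Core HMM machinery against independent oracles.

The forward-backward implementation is checked against an exhaustive
path-enumeration oracle (all K^T state paths) on small instances and against
hmmlearn's categorical HMM; Baum-Welch against the EM guarantees and
closed-form one-state solution; the supervised estimator against its
counting formulas.
"""

import itertools

import numpy as np
import pytest

from reachstates.hmm import (HMMParams, baum_welch, consistency_analysis,
                             consistent_sequences, feedforward_mask,
                             init_feedforward, posterior_decode,
                             posterior_decode_batch, supervised_fit,
                             transition_timing)


def brute_force_posteriors(pi, A, B, obs):
    """Enumerate all state paths; exact posteriors and log-likelihood."""
    T = len(obs)
    K = len(pi)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total, np.log(total)


def random_feedforward(K, M, rng, pinned=False):
    A = np.zeros((K, K))
    for i in range(K - 1):
        s = rng.uniform(0.3, 0.95)
        A[i, i], A[i, i + 1] = s, 1 - s
    A[K - 1, K - 1] = 1.0
    B = rng.dirichlet(np.ones(M), K)
    pi = np.zeros(K)
    if pinned:
        pi[0] = 1.0
    else:
        pi = rng.dirichlet(np.ones(K))
        # forward-backward accepts any pi; HMMParams only checks sum
    return HMMParams(pi, A, B)


class TestForwardBackward:
    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            K = rng.integers(1, 4)
            M = rng.integers(2, 5)
            T = rng.integers(1, 9)
            params = random_feedforward(K, M, rng)
            obs = rng.integers(0, M, T)
            trace = posterior_decode(params, obs)
            post, ll = brute_force_posteriors(params.pi, params.A, params.B, obs)
            assert np.abs(trace.gamma - post).max() < 1e-10
            assert abs(trace.loglik - ll) < 1e-10
            assert np.abs(trace.gamma.sum(1) - 1).max() < 1e-9

    def test_single_state_posterior_is_one(self):
        params = HMMParams([1.0], [[1.0]], [[0.4, 0.6]])
        trace = posterior_decode(params, [0, 1, 1, 0])
        assert np.allclose(trace.gamma, 1.0)

    def test_deterministic_private_symbols(self):
        # state 2 owns symbol 2 exclusively: posterior locks to it
        B = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        B = (B + 1e-12) / (B + 1e-12).sum(1, keepdims=True)
        params = HMMParams([1.0, 0.0], [[0.8, 0.2], [0.0, 1.0]], B)
        trace = posterior_decode(params, [0, 1, 2, 2, 2])
        assert trace.gamma[-1, 1] > 0.999

    def test_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        params = random_feedforward(3, 4, rng)
        obs = rng.integers(0, 4, (5, 50))
        gamma, ll = posterior_decode_batch(params, obs)
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = params.pi
        ref.transmat_ = params.A
        ref.emissionprob_ = params.B
        for i in range(5):
            ref_ll, ref_post = ref.score_samples(obs[i][:, None])
            assert abs(ll[i] - ref_ll) < 1e-8
            assert np.abs(gamma[i] - ref_post).max() < 1e-8

    def test_empty_sequence_rejected(self):
        params = init_feedforward(2, 3, seed=0)
        with pytest.raises(ValueError):
            posterior_decode(params, np.empty((1, 0), int))


class TestInit:
    def test_single_state(self):
        p = init_feedforward(1, 4, seed=0)
        assert np.allclose(p.A, [[1.0]])
        assert np.allclose(p.pi, [1.0])

    def test_structural_zeros(self):
        p = init_feedforward(3, 6, seed=1)
        off = ~feedforward_mask(3)
        assert (p.A[off] == 0).all()
        assert (p.A[np.triu_indices(3, 2)] == 0).all()

    def test_same_seed_identical(self):
        a = init_feedforward(4, 10, seed=7)
        b = init_feedforward(4, 10, seed=7)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.B, b.B)


class TestBaumWelch:
    def test_one_state_closed_form(self):
        # symbol 1 in 30 of 100 bins: stationary MLE is the frequency
        obs = np.zeros(100, int)
        obs[:30] = 1
        init = init_feedforward(1, 2, seed=0)
        fit, _ = baum_welch(init, obs[None, :], floor=0.0)
        assert np.allclose(fit.B, [[0.7, 0.3]], atol=1e-12)
        fit_fl, _ = baum_welch(init, obs[None, :])
        assert np.allclose(fit_fl.B, [[0.7, 0.3]], atol=1e-5)

    def test_loglik_monotone_and_mask_preserved(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(0, 5, (8, 80))
        init = init_feedforward(3, 5, seed=2)
        fit, trace = baum_welch(init, obs, max_iter=60)
        assert (np.diff(trace) >= -1e-8).all()
        assert (fit.A[~feedforward_mask(3)] == 0).all()
        assert np.abs(fit.A.sum(1) - 1).max() < 1e-9
        assert np.abs(fit.B.sum(1) - 1).max() < 1e-9

    def test_recovers_planted_emissions(self):
        # 3 planted states with distinct emission rows, strongly identifiable
        rng = np.random.default_rng(8)
        true_B = np.array([[0.8, 0.1, 0.05, 0.05],
                           [0.05, 0.8, 0.1, 0.05],
                           [0.05, 0.05, 0.1, 0.8]])
        durations = (60, 60, 60)
        seqs = []
        for _ in range(60):
            parts = [rng.choice(4, d, p=true_B[k]) for k, d in enumerate(durations)]
            seqs.append(np.concatenate(parts))
        seqs = np.array(seqs)
        best, best_ll = None, -np.inf
        for r in range(3):
            fit, trace = baum_welch(init_feedforward(3, 4, seed=r), seqs,
                                    max_iter=200)
            if trace[-1] > best_ll:
                best, best_ll = fit, trace[-1]
        assert np.abs(best.B - true_B).max() < 0.03

    def test_unseen_symbol_never_crashes(self):
        obs = np.zeros((2, 30), int)  # symbol 2 never observed
        init = init_feedforward(2, 3, seed=1)
        fit, _ = baum_welch(init, obs, max_iter=20)
        assert np.isfinite(fit.B).all()
        gamma, ll = posterior_decode_batch(fit, np.array([[0, 2, 0]]))
        assert np.isfinite(ll).all()


class TestSupervisedFit:
    def test_counting_formulas(self):
        obs = np.zeros((4, 500), int)
        obs[:, 100:110] = 2   # symbol 2 in 10 of the first-epoch bins
        labels = np.zeros((4, 500), int)
        labels[:, 250:] = 1   # epoch 0 lasts exactly 250 bins
        fit = supervised_fit(obs, labels, 2, 3, floor=0.0)
        assert fit.A[0, 1] == pytest.approx(1 / 250)
        assert fit.A[0, 0] == pytest.approx(1 - 1 / 250)
        assert fit.A[1, 1] == 1.0  # last state absorbing
        assert fit.B[0, 2] == pytest.approx(10 / 250)

    def test_epoch_without_bins_rejected(self):
        obs = np.zeros((2, 10), int)
        labels = np.zeros((2, 10), int)
        with pytest.raises(ValueError, match="no labelled bins"):
            supervised_fit(obs, labels, 2, 3)

    def test_non_monotone_labels_rejected(self):
        obs = np.zeros((1, 4), int)
        with pytest.raises(ValueError, match="non-decreasing"):
            supervised_fit(obs, np.array([[0, 1, 0, 1]]), 2, 3)

    def test_recovery_matches_generative_frequencies(self):
        rng = np.random.default_rng(11)
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6]])
        obs = np.concatenate([rng.choice(3, (50, 200), p=probs[0]),
                              rng.choice(3, (50, 200), p=probs[1])], axis=1)
        labels = np.repeat([0, 1], 200)
        fit = supervised_fit(obs, labels, 2, 3)
        assert np.abs(fit.B - probs).max() < 0.02


class TestConsistency:
    def test_threshold_crossing_rule(self):
        gamma = np.zeros((2, 10, 2))
        gamma[0, :5, 0] = 0.9
        gamma[0, 5:, 1] = 0.9
        gamma[0] += 0.05
        gamma[1, :, 0] = 0.95  # state 2 never rises
        gamma[1, :, 1] = 0.05
        mask = consistent_sequences(gamma, 0.7)
        assert mask.tolist() == [True, False]

    def test_planted_state_count_selected(self):
        # three clearly distinct planted states per target
        rng = np.random.default_rng(21)
        rows = np.array([[0.7, 0.1, 0.1, 0.1],
                         [0.1, 0.7, 0.1, 0.1],
                         [0.1, 0.1, 0.7, 0.1]])

        def make(n):
            return np.array([np.concatenate([
                rng.choice(4, 60, p=rows[k]) for k in range(3)]) for _ in range(n)])

        train = {1: make(8), 2: make(8)}
        test = {1: make(4), 2: make(4)}
        rep = consistency_analysis(train, test, 4, k_range=range(2, 5),
                                   seed=1, max_iter=80, n_restarts=2)
        assert rep.chosen_k == 3
        assert rep.fractions[3] >= 0.9


class TestTransitionTiming:
    def test_rise_index_arithmetic(self):
        gamma = np.zeros((1, 1000, 2))
        gamma[0, :450, 0] = 1.0
        gamma[0, 450:, 1] = 1.0
        tt = transition_timing(gamma, 0.7, window_start_ms=-1000, bin_ms=2.0)
        assert tt.mean_ms[1] == pytest.approx(-100.0)
        assert tt.n_risen == [1, 1]

    def test_variance_correction(self):
        rng = np.random.default_rng(2)
        n = 400
        offsets = rng.normal(0, 6, n)          # event SD 6 ms
        rises = 200 + offsets + rng.normal(0, 8, n)  # extra neural SD 8 ms
        gamma = np.zeros((n, 300, 1))
        idx = np.round(rises / 2).astype(int)
        for i, b in enumerate(idx):
            gamma[i, b:, 0] = 1.0
        tt = transition_timing(gamma, 0.7, 0.0, 2.0, event_offsets_ms=offsets)
        assert tt.corrected_sd_ms[0] == pytest.approx(8.0, abs=1.2)
        assert tt.sd_ms[0] > tt.corrected_sd_ms[0]

    def test_zero_event_variance_keeps_raw_sd(self):
        gamma = np.zeros((3, 10, 1))
        for i, b in enumerate((2, 4, 6)):
            gamma[i, b:, 0] = 1.0
        tt = transition_timing(gamma, 0.7, 0.0, 2.0)
        assert tt.corrected_sd_ms[0] == pytest.approx(tt.sd_ms[0])

    def test_never_rising_state_counted(self):
        gamma = np.zeros((2, 5, 2))
        gamma[:, :, 0] = 1.0
        tt = transition_timing(gamma, 0.7, 0.0, 2.0)
        assert tt.n_never[1] == 2 and np.isnan(tt.mean_ms[1])


from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), K=st.integers(1, 3), M=st.integers(2, 4),
       T=st.integers(1, 8))
def test_posteriors_equal_enumeration_property(seed, K, M, T):
    """Forward-backward equals the exhaustive path-sum on any small chain."""
    rng = np.random.default_rng(seed)
    params = random_feedforward(K, M, rng)
    obs = rng.integers(0, M, T)
    trace = posterior_decode(params, obs)
    post, ll = brute_force_posteriors(params.pi, params.A, params.B, obs)
    assert np.abs(trace.gamma - post).max() < 1e-10
    assert abs(trace.loglik - ll) < 1e-10
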