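"""Constrained feedforward (Bakis) hidden Markov models over symbol sequences.

States form a left-to-right chain: from state i the process can only stay or
step to i+1 (structural zeros elsewhere), matching the sequential structure
of a delayed reaching trial. Estimation is by multi-sequence Baum-Welch with
the structural zeros preserved exactly, or by direct supervised counting from
epoch-labelled bins. Decoding uses scaled forward-backward posteriors; the
initial distribution pins the process to the first state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

_ROW_TOL = 1e-9


@dataclass
class HMMParams:
    """Initial distribution, transition and emission matrices with a
    structural-zero mask for the transitions."""

    pi: np.ndarray  # (K,)
    A: np.ndarray   # (K, K)
    B: np.ndarray   # (K, M)
    mask: np.ndarray | None = None  # (K, K) bool, True = transition allowed

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, float)
        self.A = np.asarray(self.A, float)
        self.B = np.asarray(self.B, float)
        K = self.pi.shape[0]
        if self.A.shape != (K, K) or self.B.shape[0] != K:
            raise ValueError("inconsistent parameter shapes")
        if self.mask is None:
            self.mask = feedforward_mask(K)
        self.mask = np.asarray(self.mask, bool)
        if abs(self.pi.sum() - 1) > _ROW_TOL:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(1) - 1).max() > _ROW_TOL:
            raise ValueError("transition rows must sum to 1")
        if np.abs(self.B.sum(1) - 1).max() > _ROW_TOL:
            raise ValueError("emission rows must sum to 1")
        if (self.A[~self.mask] != 0).any():
            raise ValueError("transition mass outside the structural mask")

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]


@dataclass
class PosteriorTrace:
    """State posteriors (bins x states) and the sequence log-likelihood."""

    gamma: np.ndarray
    loglik: float


@dataclass
class ConsistencyReport:
    """Fraction of held-out sequences consistent with each candidate state
    count, and the chosen count (largest K whose fraction meets
    ``select_frac``; if none does, the K with the highest fraction)."""

    fractions: dict[int, float]
    chosen_k: int
    n_sequences: int
    select_frac: float = 0.9


@dataclass
class TransitionTiming:
    """Rise-time statistics of each state relative to a behavioural event."""

    state: list[int] = field(default_factory=list)
    n_risen: list[int] = field(default_factory=list)
    n_never: list[int] = field(default_factory=list)
    mean_ms: list[float] = field(default_factory=list)
    sd_ms: list[float] = field(default_factory=list)
    corrected_sd_ms: list[float] = field(default_factory=list)


def feedforward_mask(K: int) -> np.ndarray:
    """Allowed transitions of the left-to-right chain: stay or advance one."""
    mask = np.zeros((K, K), bool)
    idx = np.arange(K)
    mask[idx, idx] = True
    mask[idx[:-1], idx[:-1] + 1] = True
    return mask


def init_feedforward(K: int, M: int, seed: int = 0,
                     self_prob: float = 0.98) -> HMMParams:
    """Pseudo-random starting model: high self-transitions with jitter,
    random positive emission rows, the process pinned to state 1."""
    if K < 1 or M < 2:
        raise ValueError("need K >= 1 and M >= 2")
    rng = np.random.default_rng(seed)
    A = np.zeros((K, K))
    for i in range(K - 1):
        s = np.clip(self_prob + rng.uniform(-0.01, 0.01), 0.5, 0.999)
        A[i, i], A[i, i + 1] = s, 1 - s
    A[K - 1, K - 1] = 1.0
    B = rng.uniform(0.5, 1.5, (K, M))
    B /= B.sum(1, keepdims=True)
    pi = np.zeros(K)
    pi[0] = 1.0
    return HMMParams(pi, A, B)


@njit(cache=True)
def _estep(pi, A, B, obs):  # pragma: no cover - exercised via wrappers
    n, T = obs.shape
    K = A.shape[0]
    M = B.shape[1]
    A_num = np.zeros((K, K))
    B_num = np.zeros((K, M))
    total_ll = 0.0
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    for s in range(n):
        for j in range(K):
            alpha[0, j] = pi[j] * B[j, obs[s, 0]]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, T):
            o = obs[s, t]
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[j, o]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        total_ll += np.log(c).sum()
        for j in range(K):
            beta[T - 1, j] = 1.0
        for t in range(T - 2, -1, -1):
            o = obs[s, t + 1]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[j, o] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]
        for t in range(T):
            o = obs[s, t]
            for j in range(K):
                B_num[j, o] += alpha[t, j] * beta[t, j]
        for t in range(T - 1):
            o = obs[s, t + 1]
            for i in range(K):
                for j in range(K):
                    if A[i, j] > 0.0:
                        A_num[i, j] += (alpha[t, i] * A[i, j] * B[j, o]
                                        * beta[t + 1, j] / c[t + 1])
    return total_ll, A_num, B_num


@njit(cache=True)
def _posteriors(pi, A, B, obs):  # pragma: no cover - exercised via wrappers
    n, T = obs.shape
    K = A.shape[0]
    gamma = np.empty((n, T, K))
    ll = np.empty(n)
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    for s in range(n):
        for j in range(K):
            alpha[0, j] = pi[j] * B[j, obs[s, 0]]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, T):
            o = obs[s, t]
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[j, o]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        ll[s] = np.log(c).sum()
        for j in range(K):
            beta[T - 1, j] = 1.0
        for t in range(T - 2, -1, -1):
            o = obs[s, t + 1]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[j, o] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]
        for t in range(T):
            for j in range(K):
                gamma[s, t, j] = alpha[t, j] * beta[t, j]
    return gamma, ll


def _as_obs(sequences, M: int) -> np.ndarray:
    obs = np.asarray(sequences)
    if obs.ndim == 1:
        obs = obs[None, :]
    if obs.ndim != 2 or obs.shape[1] < 1:
        raise ValueError("sequences must be a non-empty (n, T) integer array")
    obs = obs.astype(np.int64)
    if obs.min() < 0 or obs.max() >= M:
        raise ValueError("symbols must lie in 0..M-1")
    return obs


def baum_welch(init: HMMParams, sequences, max_iter: int = 500,
               tol: float = 1e-6, floor: float = 1e-6):
    """Multi-sequence EM under the structural transition mask.

    Expected counts are accumulated over all sequences per iteration; the
    emission M-step adds ``floor`` to every entry before renormalizing so an
    unseen symbol can never zero a likelihood (needed by the neuron-loss
    experiments). Stops when the log-likelihood gain drops below ``tol`` or
    at ``max_iter``. Returns the fitted params and the log-likelihood trace.
    """
    obs = _as_obs(sequences, init.M)
    pi = init.pi.copy()
    A = init.A.copy()
    B = init.B.copy()
    mask = init.mask
    trace: list[float] = []
    for _ in range(max_iter):
        ll, A_num, B_num = _estep(pi, A, B, obs)
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            break
        trace.append(ll)
        A_num = np.where(mask, A_num, 0.0)
        row = A_num.sum(1, keepdims=True)
        A = np.where(row > 0, A_num / np.where(row > 0, row, 1.0), A)
        B_num = B_num + floor
        B = B_num / B_num.sum(1, keepdims=True)
    return HMMParams(pi, A, B, mask), np.asarray(trace)


def supervised_fit(sequences, labels, n_states: int, M: int,
                   floor: float = 1e-6) -> HMMParams:
    """Estimate a feedforward HMM directly from epoch-labelled bins.

    ``labels`` holds, per sequence and bin, the state index 0..K-1 (must be
    non-decreasing along time). The forward transition probability of state i
    is 1 / (mean number of bins spent in i); the last state is absorbing.
    Emissions are symbol frequencies within each state's bins, floored and
    renormalized.
    """
    obs = _as_obs(sequences, M)
    lab = np.asarray(labels, np.int64)
    if lab.ndim == 1:
        lab = np.broadcast_to(lab, obs.shape)
    if lab.shape != obs.shape:
        raise ValueError("labels must match sequences bin-for-bin")
    if (np.diff(lab, axis=1) < 0).any():
        raise ValueError("state labels must be non-decreasing (feedforward)")
    K = n_states
    A = np.zeros((K, K))
    B = np.zeros((K, M))
    for i in range(K):
        sel = lab == i
        per_seq = sel.sum(1)
        if per_seq.sum() == 0:
            raise ValueError(f"state {i} has no labelled bins")
        if i < K - 1:
            mean_bins = per_seq[per_seq > 0].mean()
            fwd = min(1.0 / mean_bins, 1.0)
            A[i, i], A[i, i + 1] = 1 - fwd, fwd
        else:
            A[i, i] = 1.0
        np.add.at(B[i], obs[sel], 1.0)
    B = B + floor
    B /= B.sum(1, keepdims=True)
    pi = np.zeros(K)
    pi[0] = 1.0
    return HMMParams(pi, A, B)


def posterior_decode(params: HMMParams, sequence) -> PosteriorTrace:
    """Forward-backward posteriors of one sequence (rows sum to 1)."""
    obs = _as_obs(sequence, params.M)
    if obs.shape[0] != 1:
        raise ValueError("posterior_decode takes a single sequence")
    gamma, ll = _posteriors(params.pi, params.A, params.B, obs)
    return PosteriorTrace(gamma[0], float(ll[0]))


def posterior_decode_batch(params: HMMParams, sequences):
    """Posteriors for a stack of equal-length sequences.

    Returns ``gamma`` of shape (n, T, K) and per-sequence log-likelihoods.
    """
    obs = _as_obs(sequences, params.M)
    return _posteriors(params.pi, params.A, params.B, obs)


def consistent_sequences(gamma: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Boolean mask over sequences: every state's posterior crosses
    ``threshold`` at least once."""
    return (gamma.max(axis=1) >= threshold).all(axis=1)


def consistency_analysis(train_by_target: dict, test_by_target: dict,
                         M: int, k_range=range(2, 8), threshold: float = 0.7,
                         select_frac: float = 0.9, seed: int = 0,
                         max_iter: int = 500, tol: float = 1e-6,
                         n_restarts: int = 5) -> ConsistencyReport:
    """Model-selection by posterior-threshold consistency.

    For each candidate state count K, one HMM per target is fitted on that
    target's training sequences (best of ``n_restarts`` pseudo-random EM
    initializations by likelihood) and applied to its held-out sequences; a
    sequence is consistent if all K state posteriors exceed ``threshold`` at
    least once. The chosen K is the largest whose pooled consistent fraction
    reaches ``select_frac``.
    """
    fractions: dict[int, float] = {}
    n_total = sum(np.asarray(v).shape[0] for v in test_by_target.values())
    for K in k_range:
        n_consistent = 0
        for t, train in train_by_target.items():
            best, best_ll = None, -np.inf
            for r in range(n_restarts):
                init = init_feedforward(
                    K, M, seed=seed * 1009 + 31 * K + t + 7919 * r)
                model, trace = baum_welch(init, train, max_iter=max_iter, tol=tol)
                if trace[-1] > best_ll:
                    best, best_ll = model, trace[-1]
            gamma, _ = posterior_decode_batch(best, test_by_target[t])
            n_consistent += int(consistent_sequences(gamma, threshold).sum())
        fractions[K] = n_consistent / n_total
    meeting = [k for k, f in fractions.items() if f >= select_frac]
    chosen = max(meeting) if meeting else max(fractions, key=fractions.get)
    return ConsistencyReport(fractions, chosen, n_total, select_frac)


def transition_timing(gamma: np.ndarray, threshold: float,
                      window_start_ms: float, bin_ms: float,
                      event_offsets_ms=None) -> TransitionTiming:
    """Rise-time statistics per state from posterior traces.

    The rise of a state in a sequence is the start time of the first bin in
    which its posterior exceeds ``threshold`` (ms relative to the alignment
    event). ``event_offsets_ms`` gives, per sequence, the time of a reference
    behavioural event relative to the alignment event. The reported mean is
    relative to the event's mean time; the rise SD is taken in aligned time,
    so it contains the event's own timing variability, which the corrected
    SD removes: sqrt(max(0, var_rise - var_event)). Sequences in which a
    state never rises are excluded and counted.
    """
    n, T, K = gamma.shape
    offs = np.zeros(n) if event_offsets_ms is None else np.asarray(event_offsets_ms, float)
    out = TransitionTiming()
    var_event = float(np.var(offs))
    for k in range(K):
        above = gamma[:, :, k] >= threshold
        risen = above.any(axis=1)
        first = np.argmax(above, axis=1)
        rise_ms = window_start_ms + first * bin_ms
        rel = rise_ms[risen]
        out.state.append(k)
        out.n_risen.append(int(risen.sum()))
        out.n_never.append(int((~risen).sum()))
        if risen.sum():
            v = float(np.var(rel))
            out.mean_ms.append(float(rel.mean() - offs.mean()))
            out.sd_ms.append(float(np.sqrt(v)))
            out.corrected_sd_ms.append(float(np.sqrt(max(0.0, v - var_event))))
        else:
            out.mean_ms.append(np.nan)
            out.sd_ms.append(np.nan)
            out.corrected_sd_ms.append(np.nan)
    return out
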