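"""The 28-state boosted HMM: joint (epoch, target) decoding.

Nine two-state models (FREE->DELAY, trained around cue onset) contribute an
averaged, target-independent FREE state; nine three-state models
(DELAY->MOVE->HOLD, trained around movement onset) contribute one block per
target. The merged chain starts in FREE, branches into one of nine
target-specific DELAY states and then runs forward within that target's
block; cross-target transitions and backward steps are structurally zero.
Sliding windows of the emission sequences are decoded by restarting the
process in FREE, averaging the posteriors over the window and taking the
most probable state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HMMParams, baum_welch, init_feedforward, _posteriors
from .preprocessing import EmissionSequenceSet, window_grid
from .synthetic import N_TARGETS, TrialTable

EPOCH_ORDER = ("FREE", "DELAY", "MOVE", "HOLD")
N_STATES = 1 + 3 * N_TARGETS  # 28


def state_labels() -> list[tuple[str, int]]:
    """(epoch, target) of each boosted state; target 0 means none (FREE)."""
    labels = [("FREE", 0)]
    for t in range(1, N_TARGETS + 1):
        labels += [("DELAY", t), ("MOVE", t), ("HOLD", t)]
    return labels


def state_index(epoch: str, target: int) -> int:
    """Inverse of :func:`state_labels`."""
    if epoch == "FREE":
        return 0
    return 1 + 3 * (target - 1) + ("DELAY", "MOVE", "HOLD").index(epoch)


@dataclass
class BoostedHMM:
    """28-state merged model plus the state -> (epoch, target) maps."""

    params: HMMParams
    state_epoch: tuple[str, ...]
    state_target: tuple[int, ...]

    @property
    def K(self) -> int:
        return self.params.K


def train_target_models(cue_seqs: EmissionSequenceSet,
                        move_seqs: EmissionSequenceSet,
                        seed: int = 0, max_iter: int = 500,
                        tol: float = 1e-6, n_restarts: int = 3):
    """Fit the 9 two-state (cue-aligned) and 9 three-state (movement-aligned)
    per-target HMMs by constrained Baum-Welch.

    EM is restarted ``n_restarts`` times from different pseudo-random
    initializations per model and the highest-likelihood fit is kept, which
    guards against local optima that split one behavioural state in two.
    """
    if cue_seqs.n_units != move_seqs.n_units:
        raise ValueError("segment unit counts differ")
    M = cue_seqs.n_symbols
    two, three = {}, {}
    for t in range(1, N_TARGETS + 1):
        for K, seqs, store in ((2, cue_seqs, two), (3, move_seqs, three)):
            sub = seqs.select_trials(seqs.trial_ids[seqs.target_ids == t])
            if sub.n_trials == 0:
                raise ValueError(f"no training trials for target {t}")
            best, best_ll = None, -np.inf
            for r in range(n_restarts):
                init = init_feedforward(
                    K, M, seed=seed * 10007 + 97 * K + t + 7919 * r)
                fit, trace = baum_welch(init, sub.flat(), max_iter=max_iter,
                                        tol=tol)
                if trace[-1] > best_ll:
                    best, best_ll = fit, trace[-1]
            store[t] = best
    return two, three


def merge_boosted(two_state: dict, three_state: dict) -> BoostedHMM:
    """Assemble the 28-state model from the per-target pieces.

    The FREE emission row and self-transition are the means over the nine
    two-state models' first states; the remaining FREE mass is split equally
    over the nine target-specific DELAY states. Each target's 3x3 transition
    block and emission rows are copied from its three-state model; rows are
    renormalized at the end.
    """
    targets = sorted(two_state)
    if targets != sorted(three_state) or targets != list(range(1, N_TARGETS + 1)):
        raise ValueError("need models for targets 1..9")
    Ms = {m.M for m in two_state.values()} | {m.M for m in three_state.values()}
    if len(Ms) != 1:
        raise ValueError("symbol-count mismatch across per-target models")
    M = Ms.pop()
    K = N_STATES
    A = np.zeros((K, K))
    B = np.zeros((K, M))
    mask = np.zeros((K, K), bool)

    B[0] = np.mean([two_state[t].B[0] for t in targets], axis=0)
    free_self = float(np.mean([two_state[t].A[0, 0] for t in targets]))
    A[0, 0] = free_self
    mask[0, 0] = True
    for t in targets:
        base = 1 + 3 * (t - 1)
        A[0, base] = (1.0 - free_self) / N_TARGETS
        mask[0, base] = True
        blk = three_state[t]
        A[base:base + 3, base:base + 3] = blk.A
        mask[base:base + 3, base:base + 3] = blk.mask
        B[base:base + 3] = blk.B
    A /= A.sum(1, keepdims=True)
    pi = np.zeros(K)
    pi[0] = 1.0
    labels = state_labels()
    return BoostedHMM(HMMParams(pi, A, B, mask),
                      tuple(e for e, _ in labels), tuple(t for _, t in labels))


def decode_windows(model: BoostedHMM, seqs: EmissionSequenceSet,
                   width_ms: float, step_ms: float = 10.0) -> pd.DataFrame:
    """Classify every sliding window of every sequence.

    Each window restarts the chain in FREE, is decoded by forward-backward,
    and the state with the highest bin-averaged posterior is predicted (ties
    go to the earliest state in chain order). Windows never straddle the
    seam between concatenated segments. Returns one row per
    (trial, repeat, window).
    """
    grid = window_grid(seqs, width_ms, step_ms)
    width_b = int(round(width_ms / seqs.bin_ms))
    flat = seqs.flat()
    n_seq = flat.shape[0]
    trial_ids = np.repeat(seqs.trial_ids, seqs.n_repeats)
    repeats = np.tile(np.arange(seqs.n_repeats), seqs.n_trials)
    p = model.params
    frames = []
    for si, start_b, start_ms in grid:
        obs = np.ascontiguousarray(flat[:, start_b:start_b + width_b])
        gamma, _ = _posteriors(p.pi, p.A, p.B, obs.astype(np.int64))
        pred = np.argmax(gamma.mean(axis=1), axis=1)  # argmax -> earliest tie
        frames.append(pd.DataFrame({
            "trial_id": trial_ids,
            "repeat": repeats,
            "event": seqs.segments[si].event,
            "window_start_ms": np.full(n_seq, start_ms),
            "width_ms": np.full(n_seq, float(width_ms)),
            "pred_state": pred,
        }))
    df = pd.concat(frames, ignore_index=True)
    df["pred_epoch"] = np.asarray(model.state_epoch)[df["pred_state"]]
    df["pred_target"] = np.asarray(model.state_target)[df["pred_state"]]
    return df


def assign_true_labels(windows: pd.DataFrame, trials: TrialTable) -> pd.DataFrame:
    """Attach true (epoch, target) labels by the window-midpoint rule.

    The true epoch is the epoch of the trial that contains the window
    midpoint (midpoints on an epoch boundary belong to the later epoch);
    the true target is the trial's target, or 0 for FREE windows.
    """
    out = windows.reset_index(drop=True)
    epochs = np.empty(len(out), object)
    targets = np.zeros(len(out), int)
    mid_rel = out["window_start_ms"].to_numpy() + out["width_ms"].to_numpy() / 2
    for (tid, event), idx in out.groupby(["trial_id", "event"]).groups.items():
        ev_time = float(trials.event_times(event).loc[tid])
        tgt = int(trials.trial(tid)["target_id"])
        for i in idx:
            ep = trials.epoch_of(tid, ev_time + mid_rel[i])
            epochs[i] = ep
            targets[i] = 0 if ep == "FREE" else tgt
    out["true_epoch"] = epochs
    out["true_target"] = targets
    return out
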