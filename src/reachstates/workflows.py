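"""End-to-end pipeline wiring: dataset -> sequences -> models -> reports.

These helpers glue the modules into the standard experiments: generating an
area-like synthetic population, building the training segments (cue-aligned
-500..+500 ms for the two-state models, movement-aligned -1000..+1000 ms for
the three-state models) and the decoding sequences (last 500 ms of FREE
concatenated with the movement-centred 2,000 ms), fitting the boosted HMM in
either variant, decoding sliding windows, and the consistency and
perturbation experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import boosted as bst
from .baselines import WindowFeatures, window_features
from .hmm import ConsistencyReport, consistency_analysis, supervised_fit
from .preprocessing import (align_and_bin, concat_segments, make_cv_folds,
                            symbolize)
from .synthetic import (SpikeDataset, TaskTiming, TrialTable, make_population,
                        make_task_schedule, simulate_spikes)

CUE_EVENT = "target_on_ms"
MOVE_EVENT = "movement_onset_ms"
CUE_WINDOW = (-500.0, 500.0)     # two-state training: FREE -> DELAY
MOVE_WINDOW = (-1000.0, 1000.0)  # three-state training: DELAY -> MOVE -> HOLD
FREE_WINDOW = (-500.0, 0.0)      # decoding prefix: last 500 ms before the cue


def generate_dataset(profile: str = "V6A-like", n_units: int = 40,
                     n_trials_per_target: int = 10, seed: int = 0,
                     timing: TaskTiming | None = None):
    """Population spec, trial table and spikes for one synthetic session."""
    spec = make_population(n_units, profile, seed=seed)
    trials = make_task_schedule(n_trials_per_target, timing, seed=seed + 1)
    data = simulate_spikes(spec, trials, seed=seed + 2)
    return spec, trials, data


def training_sequences(data: SpikeDataset, trial_ids, n_repeats: int,
                       seed: int, bin_ms: float = 2.0):
    """Cue-aligned and movement-aligned emission sequences for training."""
    cue = symbolize(align_and_bin(data, CUE_EVENT, CUE_WINDOW, bin_ms,
                                  trial_ids), n_repeats, seed)
    move = symbolize(align_and_bin(data, MOVE_EVENT, MOVE_WINDOW, bin_ms,
                                   trial_ids), n_repeats, seed + 1)
    return cue, move


def decoding_sequences(data: SpikeDataset, trial_ids, n_repeats: int,
                       seed: int, bin_ms: float = 2.0):
    """FREE prefix + movement-centred segment, concatenated per repeat."""
    free = symbolize(align_and_bin(data, CUE_EVENT, FREE_WINDOW, bin_ms,
                                   trial_ids), n_repeats, seed)
    move = symbolize(align_and_bin(data, MOVE_EVENT, MOVE_WINDOW, bin_ms,
                                   trial_ids), n_repeats, seed + 1)
    return concat_segments(free, move)


def epoch_bin_labels(trials: TrialTable, trial_ids, event: str,
                     window_ms, bin_ms: float, states: list[str]) -> np.ndarray:
    """State index (position in ``states``) of every bin of every trial,
    classified by bin midpoint; boundaries go to the later epoch."""
    start, end = window_ms
    n_bins = int(round((end - start) / bin_ms))
    out = np.empty((len(trial_ids), n_bins), np.int64)
    mids = start + (np.arange(n_bins) + 0.5) * bin_ms
    for i, tid in enumerate(trial_ids):
        ev = float(trials.event_times(event).loc[tid])
        for b, m in enumerate(mids):
            out[i, b] = states.index(trials.epoch_of(tid, ev + m))
    return out


def fit_boosted(data: SpikeDataset, train_ids, supervised: bool = False,
                n_repeats: int = 10, seed: int = 0, max_iter: int = 500,
                tol: float = 1e-6, bin_ms: float = 2.0) -> bst.BoostedHMM:
    """Train the 28-state boosted model, unsupervised (Baum-Welch) or
    supervised (epoch-labelled counting), and merge."""
    cue, move = training_sequences(data, train_ids, n_repeats, seed, bin_ms)
    if not supervised:
        two, three = bst.train_target_models(cue, move, seed=seed,
                                             max_iter=max_iter, tol=tol)
    else:
        two, three = {}, {}
        M = cue.n_symbols
        for t in range(1, 10):
            for store, seqs, window, event, states in (
                    (two, cue, CUE_WINDOW, CUE_EVENT, ["FREE", "DELAY"]),
                    (three, move, MOVE_WINDOW, MOVE_EVENT,
                     ["DELAY", "MOVE", "HOLD"])):
                sub = seqs.select_trials(seqs.trial_ids[seqs.target_ids == t])
                labels = epoch_bin_labels(data.trials, sub.trial_ids, event,
                                          window, bin_ms, states)
                labels = np.repeat(labels, sub.n_repeats, axis=0)
                store[t] = supervised_fit(sub.flat(), labels, len(states), M)
    return bst.merge_boosted(two, three)


def decode_report(model: bst.BoostedHMM, data: SpikeDataset, val_ids,
                  trials: TrialTable, width_ms: float = 200.0,
                  step_ms: float = 10.0, n_repeats: int = 10, seed: int = 0,
                  bin_ms: float = 2.0) -> pd.DataFrame:
    """Decode the validation trials' sliding windows and attach true labels."""
    seqs = decoding_sequences(data, val_ids, n_repeats, seed, bin_ms)
    df = bst.decode_windows(model, seqs, width_ms, step_ms)
    return bst.assign_true_labels(df, trials)


def epoch_accuracy(report: pd.DataFrame) -> float:
    return float((report["pred_epoch"] == report["true_epoch"]).mean())


def target_accuracy(report: pd.DataFrame) -> float:
    return float((report["pred_target"] == report["true_target"]).mean())


def consistency_experiment(data: SpikeDataset, seed: int = 0, fold: int = 0,
                           n_repeats_train: int = 4, n_repeats_test: int = 20,
                           k_range=range(2, 8), threshold: float = 0.7,
                           select_frac: float = 0.9, max_iter: int = 150,
                           tol: float = 1e-6,
                           bin_ms: float = 2.0) -> ConsistencyReport:
    """Optimal-state-count analysis on movement-centred sequences.

    Per-target HMMs with 2-7 states are fitted on the training trials of one
    leave-one-out fold and applied to the held-out trials; the report gives
    the consistent fraction per candidate K and the selected K.
    """
    train_ids, val_ids = make_cv_folds(data.trials)[fold]
    train = symbolize(align_and_bin(data, MOVE_EVENT, MOVE_WINDOW, bin_ms,
                                    train_ids), n_repeats_train, seed)
    test = symbolize(align_and_bin(data, MOVE_EVENT, MOVE_WINDOW, bin_ms,
                                   val_ids), n_repeats_test, seed + 1)
    train_by_t, test_by_t = {}, {}
    for t in range(1, 10):
        train_by_t[t] = train.select_trials(
            train.trial_ids[train.target_ids == t]).flat()
        test_by_t[t] = test.select_trials(
            test.trial_ids[test.target_ids == t]).flat()
    return consistency_analysis(train_by_t, test_by_t, train.n_symbols,
                                k_range=k_range, threshold=threshold,
                                select_frac=select_frac, seed=seed,
                                max_iter=max_iter, tol=tol)


def baseline_windows(data: SpikeDataset, trial_ids, width_ms: float = 200.0,
                     step_ms: float = 10.0, bin_ms: float = 2.0,
                     keep_binned: bool = True) -> tuple[WindowFeatures, np.ndarray]:
    """SVM/LSTM features over the decoding stretch plus 28-class labels."""
    segs = [align_and_bin(data, CUE_EVENT, FREE_WINDOW, bin_ms, trial_ids),
            align_and_bin(data, MOVE_EVENT, MOVE_WINDOW, bin_ms, trial_ids)]
    feats = window_features(segs, width_ms, step_ms, keep_binned=keep_binned)
    labelled = bst.assign_true_labels(feats.meta, data.trials)
    y = np.array([bst.state_index(e, t) for e, t in
                  zip(labelled["true_epoch"], labelled["true_target"])])
    feats.meta = labelled
    return feats, y


def class_epoch_target(class_ids) -> tuple[np.ndarray, np.ndarray]:
    """Decompose 28-class ids into (epoch, target) label arrays."""
    labels = bst.state_labels()
    epochs = np.array([e for e, _ in labels])
    targets = np.array([t for _, t in labels])
    class_ids = np.asarray(class_ids, int)
    return epochs[class_ids], targets[class_ids]


def run_cv_decoding(data: SpikeDataset, trials: TrialTable,
                    widths_ms=(200.0,), folds=None, supervised: bool = False,
                    n_repeats_train: int = 10, n_repeats_val: int = 10,
                    step_ms: float = 10.0, seed: int = 0, max_iter: int = 500,
                    tol: float = 1e-6) -> pd.DataFrame:
    """Cross-validated boosted-HMM decoding across window widths.

    Returns the concatenated window-level report with ``fold`` and
    ``width_ms`` columns; one model is trained per fold and reused for all
    widths.
    """
    all_folds = make_cv_folds(trials)
    if folds is None:
        folds = range(len(all_folds))
    parts = []
    for f in folds:
        train_ids, val_ids = all_folds[f]
        model = fit_boosted(data, train_ids, supervised=supervised,
                            n_repeats=n_repeats_train, seed=seed + 13 * f,
                            max_iter=max_iter, tol=tol)
        for w in widths_ms:
            rep = decode_report(model, data, val_ids, trials, width_ms=w,
                                step_ms=step_ms, n_repeats=n_repeats_val,
                                seed=seed + 31 * f)
            rep["fold"] = f
            parts.append(rep)
    return pd.concat(parts, ignore_index=True)
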