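"""Neural-state identification: optimal state count and transition timing.

For each area-like session (written by 01_simulate.py): run the consistency
analysis (2-7 candidate states on movement-centred sequences) and, for the
selected 3-state models, measure when each state's posterior first rises
above 0.7 relative to movement onset and target touch, correcting the
touch-locked transition SD for the touch-timing variability.

Writes results/neural_states.json.
"""

import json
from pathlib import Path

import numpy as np

from reachstates import workflows as wf
from reachstates.data_io import read_spike_dataset
from reachstates.hmm import (baum_welch, init_feedforward,
                             posterior_decode_batch, transition_timing)
from reachstates.preprocessing import align_and_bin, make_cv_folds, symbolize

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT.parent / "scratch" / "data"
SEED = 2


def state_timing(data, trials, seed):
    """3-state per-target fits; pooled rise statistics on held-out trials."""
    train_ids, val_ids = make_cv_folds(trials)[0]
    train = symbolize(align_and_bin(data, wf.MOVE_EVENT, wf.MOVE_WINDOW, 2.0,
                                    train_ids), 4, seed)
    test = symbolize(align_and_bin(data, wf.MOVE_EVENT, wf.MOVE_WINDOW, 2.0,
                                   val_ids), 20, seed + 1)
    gammas, offsets = [], []
    touch = trials.event_times("touch_ms") - trials.event_times("movement_onset_ms")
    for t in range(1, 10):
        tr = train.select_trials(train.trial_ids[train.target_ids == t]).flat()
        te_set = test.select_trials(test.trial_ids[test.target_ids == t])
        best, best_ll = None, -np.inf
        for r in range(5):
            fit, trace = baum_welch(init_feedforward(3, train.n_symbols,
                                                     seed=seed + 31 * t + r),
                                    tr, max_iter=150)
            if trace[-1] > best_ll:
                best, best_ll = fit, trace[-1]
        gamma, _ = posterior_decode_batch(best, te_set.flat())
        gammas.append(gamma)
        offsets.append(np.repeat(touch.loc[te_set.trial_ids].to_numpy(),
                                 te_set.n_repeats))
    gamma = np.concatenate(gammas)
    offs = np.concatenate(offsets)
    move_locked = transition_timing(gamma, 0.7, -1000.0, 2.0)
    touch_locked = transition_timing(gamma, 0.7, -1000.0, 2.0,
                                     event_offsets_ms=offs)
    return {
        "move_rise_ms": {  # MOVE state rise relative to movement onset
            "mean": move_locked.mean_ms[1], "sd": move_locked.sd_ms[1]},
        "hold_rise_vs_touch_ms": {  # HOLD state rise relative to touch
            "mean": touch_locked.mean_ms[2],
            "sd": touch_locked.sd_ms[2],
            "corrected_sd": touch_locked.corrected_sd_ms[2]},
        "n_sequences": int(gamma.shape[0]),
    }


def main() -> None:
    out = {}
    for profile in ("V6A-like", "PEc-like", "PE-like"):
        d = DATA / profile
        data, trials = read_spike_dataset(d / "spikes.csv", d / "trials.csv",
                                          d / "population.json")
        rep = wf.consistency_experiment(data, seed=SEED, max_iter=150)
        timing = state_timing(data, trials, SEED)
        out[profile] = {"consistent_fractions": rep.fractions,
                        "chosen_states": rep.chosen_k, **timing}
        print(f"{profile}: chosen {rep.chosen_k} states, fractions "
              f"{ {k: round(v, 2) for k, v in rep.fractions.items()} }")
        print(f"  MOVE rise {timing['move_rise_ms']['mean']:+.0f} ms vs movement onset; "
              f"HOLD rise {timing['hold_rise_vs_touch_ms']['mean']:+.0f} "
              f"+- {timing['hold_rise_vs_touch_ms']['corrected_sd']:.0f} ms vs touch")
    (ROOT / "neural_states.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
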