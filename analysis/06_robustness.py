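"""Decoder robustness: neuron loss and spike-shuffle noise, no retraining.

On the V6A-like session, the supervised boosted HMM, an SVM and an LSTM are
trained once on clean data, then evaluated while (a) an increasing number of
units is removed (HMM: sequences regenerated without them; SVM/LSTM: inputs
zeroed) and (b) an increasing number of units has its interior spikes
redrawn between the first and last spike of each trial. Also runs a small
population-subsampling curve with retraining (HMM only at desk scale).

Writes results/perturbation.csv and results/subsample.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reachstates import evaluation as ev
from reachstates import workflows as wf
from reachstates.baselines import lstm_fit, svm_fit, zero_units
from reachstates.data_io import read_spike_dataset
from reachstates.preprocessing import make_cv_folds

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT.parent / "scratch" / "data"
SEED = 6
KS = (2, 4, 8, 16, 32)  # 64 exceeds the 40-unit session
N_BOOT_LOSS, N_BOOT_NOISE = 5, 3


def main() -> None:
    d = DATA / "V6A-like"
    data, trials = read_spike_dataset(d / "spikes.csv", d / "trials.csv",
                                      d / "population.json")
    train_ids, val_ids = make_cv_folds(trials)[0]
    n_units = data.n_units

    model = wf.fit_boosted(data, train_ids, supervised=True, n_repeats=2,
                           seed=SEED)
    feats_tr, y_tr = wf.baseline_windows(data, train_ids, step_ms=50.0)
    feats_te, y_te = wf.baseline_windows(data, val_ids, step_ms=50.0)
    svm, _ = svm_fit(feats_tr.rates, y_tr,
                     grid={"kernel": ["poly"], "degree": [2], "C": [100.0]},
                     cv=2, seed=SEED)
    lstm = lstm_fit(feats_tr.binned, y_tr, n_classes=28, hidden=32,
                    n_iters=200, batch_size=256, seed=SEED)
    ep_true, _ = wf.class_epoch_target(y_te)

    def baseline_acc(pred):
        return float((wf.class_epoch_target(pred)[0] == ep_true).mean())

    def eval_loss(removed):
        dd = data.drop_units(removed) if len(removed) else data
        rep = wf.decode_report(model, dd, val_ids, trials, step_ms=50.0,
                               n_repeats=2, seed=SEED + 1)
        if len(removed):
            rates = zero_units(feats_te.rates, removed)
            binned = zero_units(feats_te.binned, removed)
        else:
            rates, binned = feats_te.rates, feats_te.binned
        return {"accuracy": wf.epoch_accuracy(rep),
                "svm": baseline_acc(svm.predict(rates)),
                "lstm": baseline_acc(lstm.predict(binned))}

    def eval_noise(units, seed):
        dd = ev.shuffle_spike_noise(data, units, seed) if len(units) else data
        rep = wf.decode_report(model, dd, val_ids, trials, step_ms=50.0,
                               n_repeats=2, seed=SEED + 1)
        fe, _ = wf.baseline_windows(dd, val_ids, step_ms=50.0)
        return {"accuracy": wf.epoch_accuracy(rep),
                "svm": baseline_acc(svm.predict(fe.rates)),
                "lstm": baseline_acc(lstm.predict(fe.binned))}

    loss = ev.neuron_loss(n_units, eval_loss, ks=KS, n_boot=N_BOOT_LOSS,
                          seed=SEED)
    loss["perturbation"] = "loss"
    noise = ev.noise_injection(n_units, eval_noise, ks=KS,
                               n_boot=N_BOOT_NOISE, seed=SEED)
    noise["perturbation"] = "noise"
    out = pd.concat([loss, noise], ignore_index=True)
    out.to_csv(ROOT / "perturbation.csv", index=False)
    for pert in ("loss", "noise"):
        m = out[out.perturbation == pert].groupby("k")[["accuracy", "svm", "lstm"]].mean()
        print(f"{pert}: epoch accuracy by removed/noised units\n",
              m.round(3).to_string())

    def subsample_eval(units, seed):
        dd = data.drop_units(np.setdiff1d(np.arange(1, n_units + 1), units))
        m = wf.fit_boosted(dd, train_ids, supervised=True, n_repeats=2,
                           seed=seed % (2 ** 31 - 1))
        rep = wf.decode_report(m, dd, val_ids, trials, step_ms=50.0,
                               n_repeats=2, seed=SEED + 2)
        return wf.epoch_accuracy(rep)

    curve, min_units = ev.subsample_curve(n_units, subsample_eval, step=10,
                                          n_repeats=3, seed=SEED)
    curve.to_csv(ROOT / "subsample.csv", index=False)
    print("subsample curve (epoch accuracy):\n",
          curve.groupby("size")["accuracy"].mean().round(3).to_string())
    print("minimum units for > 50% epoch accuracy:", min_units)


if __name__ == "__main__":
    main()
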