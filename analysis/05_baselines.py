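"""Algorithm comparison: SVM and LSTM against the boosted HMM.

On the V6A-like session, 200-ms windows (50-ms step at desk scale): the SVM
decodes per-unit mean rates (polynomial kernel, small C grid), the LSTM the
raw 2-ms binned counts, over the same 28 (epoch, target) classes as the
boosted HMM. Epoch and target accuracies per algorithm go to
results/baseline_accuracy.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reachstates import workflows as wf
from reachstates.baselines import lstm_fit, svm_fit
from reachstates.data_io import read_spike_dataset
from reachstates.preprocessing import make_cv_folds

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT.parent / "scratch" / "data"
SEED = 5


def main() -> None:
    d = DATA / "V6A-like"
    data, trials = read_spike_dataset(d / "spikes.csv", d / "trials.csv",
                                      d / "population.json")
    train_ids, val_ids = make_cv_folds(trials)[0]
    feats_tr, y_tr = wf.baseline_windows(data, train_ids, step_ms=50.0)
    feats_te, y_te = wf.baseline_windows(data, val_ids, step_ms=50.0)
    ep_true, tg_true = wf.class_epoch_target(y_te)

    rows = []

    def record(name, pred):
        ep, tg = wf.class_epoch_target(pred)
        rows.append({"algorithm": name,
                     "epoch_accuracy": float((ep == ep_true).mean()),
                     "target_accuracy": float((tg == tg_true).mean())})
        print(f"{name:8s} epoch {rows[-1]['epoch_accuracy']:.2f} "
              f"target {rows[-1]['target_accuracy']:.2f}")

    model = wf.fit_boosted(data, train_ids, n_repeats=5, seed=SEED,
                           max_iter=300)
    rep = wf.decode_report(model, data, val_ids, trials, step_ms=50.0,
                           n_repeats=3, seed=SEED)
    rows.append({"algorithm": "hmm",
                 "epoch_accuracy": wf.epoch_accuracy(rep),
                 "target_accuracy": wf.target_accuracy(rep)})
    print(f"hmm      epoch {rows[-1]['epoch_accuracy']:.2f} "
          f"target {rows[-1]['target_accuracy']:.2f}")

    svm, info = svm_fit(feats_tr.rates, y_tr,
                        grid={"kernel": ["poly"], "degree": [2, 3],
                              "C": [1.0, 100.0]}, cv=2, seed=SEED)
    print("svm grid choice:", info["best_params"])
    record("svm", svm.predict(feats_te.rates))

    lstm = lstm_fit(feats_tr.binned, y_tr, feats_te.binned, y_te,
                    n_classes=28, hidden=48, n_iters=300, batch_size=256,
                    seed=SEED)
    record("lstm", lstm.predict(feats_te.binned))

    pd.DataFrame(rows).to_csv(ROOT / "baseline_accuracy.csv", index=False)


if __name__ == "__main__":
    main()
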