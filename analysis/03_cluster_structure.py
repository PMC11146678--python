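"""Exploratory population-activity structure: t-SNE maps and DBI bootstraps.

Per session: standardized (trial x epoch) mean-rate vectors are embedded in
2-D for visualization, and the Davies-Bouldin index for epoch and target
clusterings is bootstrapped over unit subsets in both modes (90% of units;
fixed 40 units). Higher DBI = more cluster overlap = harder decoding.

Writes results/dbi.csv and results/tsne_<profile>.png.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from reachstates.data_io import read_spike_dataset
from reachstates.evaluation import (bootstrap_dbi, embed_2d, epoch_rate_matrix,
                                    standardize)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT.parent / "scratch" / "data"
SEED = 3
N_BOOT = 200  # desk-scale bootstrap


def main() -> None:
    rows = []
    for profile in ("V6A-like", "PEc-like", "PE-like"):
        d = DATA / profile
        data, trials = read_spike_dataset(d / "spikes.csv", d / "trials.csv",
                                          d / "population.json")
        X, epochs, targets, _ = epoch_rate_matrix(data, trials)
        Z = standardize(X)

        emb = embed_2d(X, seed=SEED)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, labels, title in ((axes[0], epochs, "task phase"),
                                  (axes[1], targets, "target")):
            for lab in np.unique(labels):
                sel = labels == lab
                ax.scatter(emb[sel, 0], emb[sel, 1], s=8, label=str(lab))
            ax.set_title(f"{profile}: {title}")
            ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(ROOT / f"tsne_{profile}.png", dpi=120)
        plt.close(fig)

        for mode, kw in (("fraction", {}), ("fixed", {"fixed_units": 40})):
            for name, labels in (("epoch", epochs), ("target", targets)):
                s = bootstrap_dbi(Z, labels, mode=mode, n_boot=N_BOOT,
                                  seed=SEED, **kw)
                s = s[np.isfinite(s)]
                rows.append({"profile": profile, "mode": mode, "labels": name,
                             "dbi_mean": s.mean(), "dbi_sd": s.std(),
                             "n_boot": len(s)})
                print(f"{profile} {name:6s} DBI ({mode}): "
                      f"{s.mean():.2f} +- {s.std():.2f}")
    pd.DataFrame(rows).to_csv(ROOT / "dbi.csv", index=False)


if __name__ == "__main__":
    main()
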