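"""Generate the three area-like synthetic sessions used by the analyses.

Writes one directory per preset (V6A-like, PEc-like, PE-like) under
results/data/: spikes.csv, trials.csv and the generating population spec.
Each session has 40 units and 10 correct trials per target — the scale of
the smaller populations this kind of analysis runs on.
"""

from pathlib import Path

from reachstates import workflows as wf
from reachstates.data_io import write_spike_dataset

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
SEED = 1


def main() -> None:
    for i, profile in enumerate(("V6A-like", "PEc-like", "PE-like")):
        spec, trials, data = wf.generate_dataset(profile, n_units=40,
                                                 n_trials_per_target=10,
                                                 seed=SEED + 100 * i)
        out = OUT / profile
        write_spike_dataset(data, out, spec)
        rate = len(data.spikes) / (len(trials) * 40) / (
            trials.df["target_off_ms"].mean() / 1000)
        print(f"{profile}: {len(data.spikes)} spikes, "
              f"grand-mean rate {rate:.1f} sp/s -> {out}")


if __name__ == "__main__":
    main()
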