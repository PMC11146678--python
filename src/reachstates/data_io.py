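"""File formats and run configuration.

Spike data travel as two CSVs — ``spikes.csv`` (unit_id, trial_id, time_ms)
and ``trials.csv`` (trial_id, target_id, six event columns) — with times at
0.1-ms resolution, plus an optional JSON sidecar for the generating
population. The run configuration carries the analysis defaults (2-ms bins,
100 emission sequences per trial, window widths 50-300 ms at a 10-ms step,
consistency threshold 0.7, Baum-Welch stopping at 500 iterations or a
log-likelihood change below 1e-6).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import EVENT_COLUMNS, PopulationSpec, SpikeDataset, TrialTable

log = logging.getLogger("reachstates")


class IntegrityError(ValueError):
    """Referential integrity violation between spike and trial tables."""


class ConfigError(ValueError):
    """Invalid or unknown run-configuration values."""


@dataclass(frozen=True)
class RunConfig:
    """Analysis defaults; every field can be overridden from YAML."""

    bin_ms: float = 2.0
    n_repeats: int = 100
    window_widths_ms: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
    window_step_ms: float = 10.0
    consistency_threshold: float = 0.7
    max_iter: int = 500
    tol: float = 1e-6
    cv: str = "leave-one-out"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ConfigError("bin_ms must be > 0")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not 0 < self.consistency_threshold < 1:
            raise ConfigError("consistency_threshold must be in (0, 1)")
        if self.max_iter < 1 or self.tol <= 0:
            raise ConfigError("max_iter must be >= 1 and tol > 0")
        if self.window_step_ms <= 0 or any(w <= 0 for w in self.window_widths_ms):
            raise ConfigError("window widths and step must be positive")

    def hash(self) -> str:
        """Stable hash of the configuration; equal hashes => identical runs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "window_widths_ms" in data:
        data["window_widths_ms"] = tuple(float(w) for w in data["window_widths_ms"])
    try:
        return RunConfig(**data)
    except TypeError as exc:  # wrong value type
        raise ConfigError(str(exc)) from exc


def write_spike_dataset(dataset: SpikeDataset, out_dir: str | Path,
                        spec: PopulationSpec | None = None) -> None:
    """Write spikes.csv / trials.csv (and population.json if a spec is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes = dataset.spikes.copy()
    spikes["time_ms"] = spikes["time_ms"].round(1)
    spikes.to_csv(out / "spikes.csv", index=False, float_format="%.1f")
    trials = dataset.trials.df.copy()
    trials.to_csv(out / "trials.csv", index=False, float_format="%.1f")
    meta = {"n_units": dataset.n_units, "area": dataset.area}
    if spec is not None:
        meta["population"] = {
            "baseline_rate": spec.baseline_rate.tolist(),
            "epoch_gain": spec.epoch_gain.tolist(),
            "target_tuning": spec.target_tuning.tolist(),
            "area_profile": spec.area_profile,
            "rate_cap": spec.rate_cap,
        }
    (out / "population.json").write_text(json.dumps(meta))


def read_spike_dataset(spikes_path: str | Path,
                       trials_path: str | Path,
                       meta_path: str | Path | None = None,
                       n_units: int | None = None) -> tuple[SpikeDataset, TrialTable]:
    """Read the CSV pair back; round-trips the writer bit-exactly at 0.1 ms.

    A spike referencing a missing trial raises :class:`IntegrityError`;
    unsorted spike times are repaired with a warning.
    """
    trials_df = pd.read_csv(trials_path)
    trials = TrialTable(trials_df)
    spikes = pd.read_csv(spikes_path)
    if spikes.empty:
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    spikes["time_ms"] = spikes["time_ms"].astype(float).round(1)

    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    if n_units is None:
        n_units = meta.get("n_units")
    if n_units is None:
        n_units = int(spikes["unit_id"].max()) if len(spikes) else 0

    if len(spikes):
        missing = set(spikes["trial_id"]) - set(trials.trial_ids)
        if missing:
            raise IntegrityError(
                f"spikes reference unknown trials: {sorted(missing)[:5]}")
        grouped = spikes.groupby(["trial_id", "unit_id"])["time_ms"]
        if (grouped.apply(lambda s: (np.diff(s.to_numpy()) < 0).any())).any():
            warnings.warn("unsorted spike times repaired", stacklevel=2)
    dataset = SpikeDataset(spikes, n_units, trials, meta.get("area", "custom"))
    return dataset, trials


def read_population_spec(meta_path: str | Path) -> PopulationSpec:
    meta = json.loads(Path(meta_path).read_text())
    if "population" not in meta:
        raise IntegrityError("population.json has no population entry")
    p = meta["population"]
    return PopulationSpec(
        np.array(p["baseline_rate"]), np.array(p["epoch_gain"]),
        np.array(p["target_tuning"]), p["area_profile"], p["rate_cap"])
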