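"""Task-structured synthetic spiking populations.

Emulates a 9-target (3 directions x 3 depths) foveated delayed reaching task:
each trial runs through FREE (home-button press, pre-cue), DELAY (target
fixation), MOVE (reach) and HOLD (target touch maintained) epochs. Units are
inhomogeneous Poisson processes whose rate in each epoch is

    rate = baseline * epoch_gain[epoch] * target_tuning[target]

with target tuning applied only after the cue (DELAY/MOVE/HOLD); during FREE
the upcoming target is unknown to the subject, so tuning is inactive.

Three area-like presets capture the qualitative contrasts between the
superior parietal areas: ``V6A-like`` (strong target tuning), ``PEc-like``
(strong epoch separation, intermediate tuning) and ``PE-like`` (weak target
tuning and FREE ~ HOLD firing similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCHS = ("FREE", "DELAY", "MOVE", "HOLD")
N_TARGETS = 9

#: event columns of a trial table, in temporal order
EVENT_COLUMNS = (
    "home_press_ms",
    "target_on_ms",
    "go_ms",
    "movement_onset_ms",
    "touch_ms",
    "target_off_ms",
)

#: behavioural event delimiting the start of each epoch
EPOCH_START_EVENT = {
    "FREE": "home_press_ms",
    "DELAY": "target_on_ms",
    "MOVE": "movement_onset_ms",
    "HOLD": "touch_ms",
}


@dataclass(frozen=True)
class TaskTiming:
    """Epoch-duration protocol of the delayed reaching task (all ms).

    Defaults follow the task protocol: a fixed 1,000-ms free period before
    cue onset, an instructed delay drawn uniformly from 1,800-2,300 ms, and a
    hold of 800-1,200 ms. Movement duration is drawn uniformly from a range
    centred on 360 ms; the reaction time (go signal to movement onset) is
    drawn from 200-400 ms, within the task's 1-s reach limit.
    """

    free_ms: float = 1000.0
    delay_range_ms: tuple[float, float] = (1800.0, 2300.0)
    reaction_range_ms: tuple[float, float] = (200.0, 400.0)
    movement_range_ms: tuple[float, float] = (240.0, 480.0)
    hold_range_ms: tuple[float, float] = (800.0, 1200.0)

    def __post_init__(self) -> None:
        if self.free_ms <= 0:
            raise ValueError("free_ms must be positive")
        for name in ("delay_range_ms", "reaction_range_ms",
                     "movement_range_ms", "hold_range_ms"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} must be positive")
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")


class TrialTable:
    """Per-trial behavioural events and target ids.

    Wraps a DataFrame with columns ``trial_id``, ``target_id`` and the six
    event times of :data:`EVENT_COLUMNS` (ms, relative to home press at 0).
    """

    def __init__(self, df: pd.DataFrame):
        required = ["trial_id", "target_id", *EVENT_COLUMNS]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        df = df[required].reset_index(drop=True)
        if df["trial_id"].duplicated().any():
            raise ValueError("duplicate trial ids")
        if not df["target_id"].between(1, N_TARGETS).all():
            raise ValueError("target ids must be in 1..9")
        events = df[list(EVENT_COLUMNS)].to_numpy(float)
        if not (np.diff(events, axis=1) > 0).all():
            raise ValueError("event times must be strictly increasing per trial")
        self.df = df
        self._by_id = df.set_index("trial_id")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.df["trial_id"].to_numpy()

    @property
    def target_ids(self) -> np.ndarray:
        return self.df["target_id"].to_numpy()

    def trial(self, trial_id: int) -> pd.Series:
        return self._by_id.loc[trial_id]

    def event_times(self, event: str) -> pd.Series:
        """Times of one event indexed by trial id."""
        if event not in EVENT_COLUMNS:
            raise KeyError(f"unknown event {event!r}")
        return self._by_id[event]

    def epoch_bounds(self, trial_id: int) -> dict[str, tuple[float, float]]:
        """Half-open [start, end) bounds of the four epochs of one trial."""
        row = self.trial(trial_id)
        edges = [row[c] for c in EVENT_COLUMNS]
        # go -> movement onset (reaction) is part of DELAY: the instructed
        # target is being withheld until the arm starts moving.
        return {
            "FREE": (edges[0], edges[1]),
            "DELAY": (edges[1], edges[3]),
            "MOVE": (edges[3], edges[4]),
            "HOLD": (edges[4], edges[5]),
        }

    def epoch_of(self, trial_id: int, t_ms: float) -> str:
        """Epoch containing time ``t_ms``; boundary times go to the later epoch."""
        bounds = self.epoch_bounds(trial_id)
        for name in reversed(EPOCHS):
            lo, hi = bounds[name]
            if lo <= t_ms < hi:
                return name
        raise ValueError(f"time {t_ms} ms outside trial {trial_id}")


@dataclass
class PopulationSpec:
    """Rate parameters of a synthetic population.

    ``baseline_rate`` (sp/s) has shape (n_units,), ``epoch_gain`` shape
    (n_units, 4) ordered as :data:`EPOCHS`, ``target_tuning`` shape
    (n_units, 9) with mean 1 per unit. Unit ids are 1..n_units.
    """

    baseline_rate: np.ndarray
    epoch_gain: np.ndarray
    target_tuning: np.ndarray
    area_profile: str = "custom"
    rate_cap: float = 100.0

    def __post_init__(self) -> None:
        self.baseline_rate = np.asarray(self.baseline_rate, float)
        self.epoch_gain = np.asarray(self.epoch_gain, float)
        self.target_tuning = np.asarray(self.target_tuning, float)
        n = self.baseline_rate.shape[0]
        if self.epoch_gain.shape != (n, len(EPOCHS)):
            raise ValueError("epoch_gain must have shape (n_units, 4)")
        if self.target_tuning.shape != (n, N_TARGETS):
            raise ValueError("target_tuning must have shape (n_units, 9)")
        if (self.baseline_rate < 0).any():
            raise ValueError("baseline rates must be >= 0")
        if (self.epoch_gain <= 0).any() or (self.target_tuning <= 0).any():
            raise ValueError("gains and tunings must be strictly positive")

    @property
    def n_units(self) -> int:
        return self.baseline_rate.shape[0]

    def rates(self, epoch: str, target_id: int) -> np.ndarray:
        """Firing rate (sp/s) of every unit in one epoch of a trial to ``target_id``."""
        e = EPOCHS.index(epoch)
        tuning = self.target_tuning[:, target_id - 1] if epoch != "FREE" else 1.0
        r = self.baseline_rate * self.epoch_gain[:, e] * tuning
        return np.minimum(r, self.rate_cap)


class SpikeDataset:
    """Spike times (ms, 0.1-ms resolution) per unit and trial.

    ``spikes`` is a DataFrame with columns ``unit_id``, ``trial_id``,
    ``time_ms`` sorted by (trial, unit, time); ``n_units`` fixes the symbol
    alphabet even for silent units.
    """

    def __init__(self, spikes: pd.DataFrame, n_units: int, trials: TrialTable,
                 area: str = "custom"):
        required = {"unit_id", "trial_id", "time_ms"}
        if not required <= set(spikes.columns):
            raise ValueError(f"spike table needs columns {sorted(required)}")
        spikes = spikes.reset_index(drop=True)
        if len(spikes):
            if not spikes["unit_id"].between(1, n_units).all():
                raise ValueError("unit ids must be in 1..n_units")
            unknown = set(spikes["trial_id"]) - set(trials.trial_ids)
            if unknown:
                raise ValueError(
                    f"spikes reference trials absent from the trial table: {sorted(unknown)[:5]}")
        self.spikes = spikes.sort_values(
            ["trial_id", "unit_id", "time_ms"], kind="stable").reset_index(drop=True)
        self.n_units = int(n_units)
        self.trials = trials
        self.area = area

    def drop_units(self, unit_ids) -> "SpikeDataset":
        """Remove the spikes of ``unit_ids`` but keep the symbol alphabet intact.

        Used for the neuron-loss experiments: downstream models still expect
        the original alphabet, the removed units simply never fire.
        """
        unit_ids = set(int(u) for u in unit_ids)
        kept = self.spikes[~self.spikes["unit_id"].isin(unit_ids)]
        return SpikeDataset(kept, self.n_units, self.trials, self.area)


def make_task_schedule(n_trials_per_target: int,
                       timing: TaskTiming | None = None,
                       seed: int = 0) -> TrialTable:
    """Draw a full trial table: ``9 * n_trials_per_target`` correct trials.

    Epoch durations are drawn uniformly from the ranges in ``timing``;
    the cue comes on exactly ``free_ms`` after the home press. Deterministic
    given ``seed``.
    """
    if n_trials_per_target < 1:
        raise ValueError("n_trials_per_target must be >= 1")
    timing = timing or TaskTiming()
    rng = np.random.default_rng(seed)
    n = N_TARGETS * n_trials_per_target
    targets = np.tile(np.arange(1, N_TARGETS + 1), n_trials_per_target)
    delay = rng.uniform(*timing.delay_range_ms, n)
    react = rng.uniform(*timing.reaction_range_ms, n)
    move = rng.uniform(*timing.movement_range_ms, n)
    hold = rng.uniform(*timing.hold_range_ms, n)
    target_on = np.full(n, timing.free_ms)
    go = target_on + delay
    mv = go + react
    touch = mv + move
    off = touch + hold
    df = pd.DataFrame({
        "trial_id": np.arange(1, n + 1),
        "target_id": targets,
        "home_press_ms": np.zeros(n),
        "target_on_ms": target_on,
        "go_ms": go,
        "movement_onset_ms": mv,
        "touch_ms": touch,
        "target_off_ms": off,
    })
    for c in EVENT_COLUMNS:
        df[c] = np.round(df[c], 1)
    return TrialTable(df)


# Per-profile draw parameters. Epoch gains are lognormal around per-epoch
# centres: ``epoch_sigma`` sets the per-unit heterogeneity of epoch
# preference (mixtures of fixation-, reach- and hold-preferring cells), which
# is what carries most of the epoch information in the symbol alphabet. The
# amplitude of the spatial tuning bump orders the areas' target information
# (V6A > PEc > PE); the PE-like preset additionally ties the HOLD gain to the
# FREE gain, giving the FREE/HOLD population similarity characteristic of PE.
_PROFILES = {
    "V6A-like": dict(tuning_amp=(2.5, 5.0), epoch_sigma=0.55,
                     centers=dict(FREE=0.8, DELAY=1.6, MOVE=2.4, HOLD=0.5),
                     hold_like_free=False),
    "PEc-like": dict(tuning_amp=(1.2, 2.5), epoch_sigma=0.65,
                     centers=dict(FREE=0.8, DELAY=1.8, MOVE=3.0, HOLD=0.4),
                     hold_like_free=False),
    "PE-like": dict(tuning_amp=(0.2, 0.6), epoch_sigma=0.3,
                    centers=dict(FREE=1.0, DELAY=1.2, MOVE=1.8, HOLD=1.0),
                    hold_like_free=True),
    "custom": dict(tuning_amp=(0.0, 0.0), epoch_sigma=0.0,
                   centers=dict(FREE=1.0, DELAY=1.0, MOVE=1.0, HOLD=1.0),
                   hold_like_free=False),
}

#: spatial tuning bump width (cm) over the target workspace
_TUNING_SIGMA_CM = 3.5


def target_positions_cm() -> np.ndarray:
    """Workspace positions of the 9 targets, shape (9, 2), cm.

    Targets sit at version angles -15/0/+15 deg and radial distances
    10 (near), 15 (intermediate), 25 (far) cm from the eyes; position is
    (d*sin(version), d*cos(version)) in the horizontal eye-level plane.
    Ids 1..9 run left-to-right within rows near, intermediate, far.
    """
    versions = np.deg2rad([-15.0, 0.0, 15.0])
    depths = [10.0, 15.0, 25.0]
    pos = [(d * np.sin(v), d * np.cos(v)) for d in depths for v in versions]
    return np.array(pos)


def make_population(n_units: int, area_profile: str = "V6A-like",
                    seed: int = 0, rate_cap: float = 100.0,
                    baseline_log_mean: float = 2.0,
                    baseline_log_sd: float = 0.5) -> PopulationSpec:
    """Draw per-unit baseline rates, epoch gains and smooth target tunings.

    Tuning is a 2-D Gaussian bump (sigma 8 cm) over the physical target
    layout with a random per-unit centre, normalized to mean 1 over targets,
    so nearby targets drive correlated rates. Baselines are lognormal
    (median ~7.4 sp/s). Deterministic given ``seed``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if area_profile not in _PROFILES:
        raise ValueError(
            f"unknown area profile {area_profile!r}; choose from {sorted(_PROFILES)}")
    p = _PROFILES[area_profile]
    rng = np.random.default_rng(seed)
    baseline = np.minimum(
        rng.lognormal(baseline_log_mean, baseline_log_sd, n_units), rate_cap)

    gains = np.empty((n_units, len(EPOCHS)))
    sig = p["epoch_sigma"]
    for e, name in enumerate(EPOCHS):
        gains[:, e] = p["centers"][name] * rng.lognormal(0.0, sig, n_units) \
            if sig > 0 else p["centers"][name]
    if p["hold_like_free"]:
        gains[:, 3] = gains[:, 0] * rng.uniform(0.95, 1.05, n_units)

    pos = target_positions_cm()
    lo, hi = pos.min(0), pos.max(0)
    centres = rng.uniform(lo, hi, (n_units, 2))
    amp = rng.uniform(*p["tuning_amp"], n_units)
    d2 = ((pos[None, :, :] - centres[:, None, :]) ** 2).sum(-1)
    tuning = 1.0 + amp[:, None] * np.exp(-d2 / (2 * _TUNING_SIGMA_CM ** 2))
    tuning /= tuning.mean(axis=1, keepdims=True)
    return PopulationSpec(baseline, gains, tuning, area_profile, rate_cap)


def simulate_spikes(spec: PopulationSpec, trials: TrialTable,
                    seed: int = 0) -> SpikeDataset:
    """Simulate epoch-wise homogeneous Poisson spiking for every trial.

    Within each epoch of each trial, unit ``u`` fires as a Poisson process at
    ``spec.rates(epoch, target)[u]``; spike times are uniform over the epoch,
    rounded to 0.1 ms and sorted. Randomness is split into one independent
    substream per (trial, unit) via ``numpy.random.SeedSequence.spawn``, so
    the generator is bit-reproducible given ``seed``.
    """
    root = np.random.SeedSequence(seed)
    trial_streams = root.spawn(len(trials))
    rows_unit, rows_trial, rows_time = [], [], []
    for row, ss in zip(trials.df.itertuples(index=False), trial_streams):
        unit_streams = ss.spawn(spec.n_units)
        bounds = trials.epoch_bounds(row.trial_id)
        rates = {e: spec.rates(e, row.target_id) for e in EPOCHS}
        for u, uss in enumerate(unit_streams):
            rng = np.random.default_rng(uss)
            times = []
            for e in EPOCHS:
                lo, hi = bounds[e]
                lam = rates[e][u] * (hi - lo) / 1000.0
                k = rng.poisson(lam)
                if k:
                    times.append(rng.uniform(lo, hi, k))
            if times:
                t = np.round(np.sort(np.concatenate(times)), 1)
                rows_unit.append(np.full(t.size, u + 1))
                rows_trial.append(np.full(t.size, row.trial_id))
                rows_time.append(t)
    if rows_unit:
        spikes = pd.DataFrame({
            "unit_id": np.concatenate(rows_unit).astype(int),
            "trial_id": np.concatenate(rows_trial).astype(int),
            "time_ms": np.concatenate(rows_time),
        })
    else:
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    return SpikeDataset(spikes, spec.n_units, trials, spec.area_profile)
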