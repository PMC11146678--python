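"""Binned counts, stochastic emission sequences and cross-validation folds.

The HMM alphabet has one symbol per unit plus silence: in every 2-ms bin a
sequence holds 0 if no unit fired, or the id of the unit that fired. When
several units fired in the same bin one of them is chosen uniformly at
random, and the draw is repeated to give 100 sequences per trial, which
together preserve the information lost by single-bin collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import SpikeDataset, TrialTable

_RES = 10  # integer time grid: 0.1 ms per tick


@dataclass(frozen=True)
class Segment:
    """One aligned stretch of bins: ``n_bins`` from ``window_start_ms``
    relative to the trial event ``event``."""

    event: str
    window_start_ms: float
    n_bins: int


@dataclass
class BinnedCounts:
    """Per-trial (units x bins) spike counts aligned to a trial event."""

    counts: np.ndarray  # (n_trials, n_units, n_bins) int
    trial_ids: np.ndarray
    target_ids: np.ndarray
    event: str
    window_ms: tuple[float, float]
    bin_ms: float

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


@dataclass
class EmissionSequenceSet:
    """Stacks of symbol sequences: shape (n_trials, n_repeats, n_bins).

    Symbols are in ``0..n_units``; ``segments`` records the aligned stretches
    the bin axis is made of (more than one after concatenation), which lets
    windows be mapped back to trial time and keeps them off the seam.
    """

    symbols: np.ndarray  # int16
    trial_ids: np.ndarray
    target_ids: np.ndarray
    n_units: int
    bin_ms: float
    segments: tuple[Segment, ...]

    @property
    def n_symbols(self) -> int:
        return self.n_units + 1

    @property
    def n_trials(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.symbols.shape[1]

    @property
    def n_bins(self) -> int:
        return self.symbols.shape[2]

    def segment_starts(self) -> np.ndarray:
        """Global bin index at which each segment starts."""
        sizes = [s.n_bins for s in self.segments]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)

    def flat(self) -> np.ndarray:
        """Sequences as one (n_trials * n_repeats, n_bins) array."""
        return self.symbols.reshape(-1, self.n_bins)

    def select_trials(self, trial_ids) -> "EmissionSequenceSet":
        idx = np.flatnonzero(np.isin(self.trial_ids, np.asarray(trial_ids)))
        return replace(self, symbols=self.symbols[idx],
                       trial_ids=self.trial_ids[idx],
                       target_ids=self.target_ids[idx])


def align_and_bin(data: SpikeDataset, event: str,
                  window_ms: tuple[float, float],
                  bin_ms: float = 2.0,
                  trial_ids=None) -> BinnedCounts:
    """Bin spikes into half-open [start, start+bin) windows around ``event``.

    ``window_ms`` is (start, end) relative to the event; its length must be an
    exact multiple of ``bin_ms``. Times are handled on a 0.1-ms integer grid,
    so bin edges are exact.
    """
    start, end = window_ms
    n_bins_f = (end - start) / bin_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("window length must be a positive multiple of bin_ms")
    trials = data.trials
    if trial_ids is None:
        trial_ids = trials.trial_ids
    trial_ids = np.asarray(trial_ids)
    ev = trials.event_times(event).loc[trial_ids].to_numpy()
    targets = trials.df.set_index("trial_id").loc[trial_ids, "target_id"].to_numpy()

    bin_ticks = int(round(bin_ms * _RES))
    counts = np.zeros((len(trial_ids), data.n_units, n_bins), dtype=np.int32)
    sp = data.spikes
    by_trial = dict(tuple(sp.groupby("trial_id"))) if len(sp) else {}
    for i, (tid, e) in enumerate(zip(trial_ids, ev)):
        g = by_trial.get(tid)
        if g is None:
            continue
        t_ticks = np.round(g["time_ms"].to_numpy() * _RES).astype(np.int64)
        rel = t_ticks - int(round((e + start) * _RES))
        idx = rel // bin_ticks
        ok = (rel >= 0) & (idx < n_bins)
        np.add.at(counts[i], (g["unit_id"].to_numpy()[ok] - 1, idx[ok]), 1)
    return BinnedCounts(counts, trial_ids, targets, event, (start, end), bin_ms)


def symbolize(counts: BinnedCounts, n_repeats: int = 100,
              seed: int = 0) -> EmissionSequenceSet:
    """Draw ``n_repeats`` symbol sequences per trial from binned counts.

    Per repeat and bin: 0 if all units silent; the active unit's id if exactly
    one fired; otherwise a uniform choice among the active units (independent
    across repeats). Deterministic given ``seed``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    n_trials, n_units, n_bins = counts.counts.shape
    out = np.zeros((n_trials, n_repeats, n_bins), dtype=np.int16)
    for i in range(n_trials):
        c = counts.counts[i] > 0  # unit fired at least once in the bin
        n_active = c.sum(axis=0)
        single = n_active == 1
        if single.any():
            out[i, :, single] = (np.argmax(c[:, single], axis=0) + 1)[:, None]
        for b in np.flatnonzero(n_active >= 2):
            active = np.flatnonzero(c[:, b]) + 1
            out[i, :, b] = active[rng.integers(0, active.size, n_repeats)]
    seg = Segment(counts.event, counts.window_ms[0], n_bins)
    return EmissionSequenceSet(out, counts.trial_ids.copy(),
                               counts.target_ids.copy(), n_units,
                               counts.bin_ms, (seg,))


def concat_segments(first: EmissionSequenceSet,
                    second: EmissionSequenceSet) -> EmissionSequenceSet:
    """Join two sequence sets bin-wise: repeat r of the output is repeat r of
    ``first`` followed by repeat r of ``second``."""
    if not np.array_equal(first.trial_ids, second.trial_ids):
        raise ValueError("segments cover different trials")
    if first.n_repeats != second.n_repeats:
        raise ValueError("repeat counts differ")
    if first.bin_ms != second.bin_ms or first.n_units != second.n_units:
        raise ValueError("bin width / unit count mismatch")
    symbols = np.concatenate([first.symbols, second.symbols], axis=2)
    return EmissionSequenceSet(symbols, first.trial_ids.copy(),
                               first.target_ids.copy(), first.n_units,
                               first.bin_ms, first.segments + second.segments)


def make_cv_folds(trials: TrialTable) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-trial-per-target-out folds.

    With n trials per target (equal across targets, default 10) returns n
    folds; fold k holds out the k-th trial of every target. Train/validation
    are disjoint and the validation sets partition all trials.
    """
    df = trials.df
    per_target = [df.loc[df["target_id"] == t, "trial_id"].to_numpy()
                  for t in sorted(df["target_id"].unique())]
    sizes = {len(ids) for ids in per_target}
    if len(sizes) != 1:
        raise ValueError("unequal trial counts per target")
    n_folds = sizes.pop()
    folds = []
    all_ids = trials.trial_ids
    for k in range(n_folds):
        val = np.array([ids[k] for ids in per_target])
        train = all_ids[~np.isin(all_ids, val)]
        folds.append((train, val))
    return folds


def window_grid(seqs: EmissionSequenceSet, width_ms: float,
                step_ms: float = 10.0) -> list[tuple[int, int, float]]:
    """Sliding-window start positions that never straddle a segment seam.

    Returns tuples ``(segment_index, global_start_bin, start_ms)`` where
    ``start_ms`` is relative to the segment's alignment event. Width and step
    must be multiples of the bin width.
    """
    def _bins(ms: float) -> int:
        b = ms / seqs.bin_ms
        if abs(b - round(b)) > 1e-9:
            raise ValueError("width/step must be multiples of bin_ms")
        return int(round(b))

    width_b, step_b = _bins(width_ms), _bins(step_ms)
    if width_b < 1:
        raise ValueError("window shorter than one bin")
    out = []
    for si, (seg, s0) in enumerate(zip(seqs.segments, seqs.segment_starts())):
        for local in range(0, seg.n_bins - width_b + 1, step_b):
            out.append((si, s0 + local,
                        seg.window_start_ms + local * seqs.bin_ms))
    return out
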