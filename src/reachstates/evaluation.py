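"""Metrics, clustering indices, perturbation experiments and statistics.

Covers: accuracy with a label-shuffle chance distribution, row-normalized
confusion matrices, directional error patterns over the FREE < DELAY < MOVE
< HOLD epoch order, the physical target geometry and the distance-confusion
correlation, the Davies-Bouldin index (1979 definition) with its underlying
R metric and unit-resampling bootstrap, neuron-dropping / noise-injection
loops, the decoding time course, rank tests, and a 2-D t-SNE embedding of
population activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import EPOCHS, N_TARGETS, SpikeDataset, TrialTable, target_positions_cm

log = logging.getLogger("reachstates")

EPOCH_RANK = {e: i for i, e in enumerate(EPOCHS)}


# ---------------------------------------------------------------------------
# accuracy, confusion, error patterns
# ---------------------------------------------------------------------------

def accuracy_and_chance(pred, true, n_shuffles: int = 1000, seed: int = 0):
    """Accuracy plus a chance distribution from shuffled true labels.

    Returns ``(accuracy, chance_samples, chance_threshold)`` where the
    threshold is the 95th percentile of the 1,000 (by default) shuffled
    accuracies.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("pred/true must be equal-length non-empty vectors")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    acc = float(np.mean(pred == true))
    rng = np.random.default_rng(seed)
    samples = np.empty(n_shuffles)
    for i in range(n_shuffles):
        samples[i] = np.mean(pred == rng.permutation(true))
    return acc, samples, float(np.percentile(samples, 95))


@dataclass
class ConfusionMatrix:
    """Counts (rows = true, columns = predicted) plus a row-normalized view."""

    labels: list
    counts: np.ndarray
    normalized: np.ndarray
    zero_rows: list

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(pred, true, labels) -> ConfusionMatrix:
    """Confusion matrix over an explicit label order; classes absent from
    ``true`` produce flagged zero rows rather than being dropped."""
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for p, t in zip(pred, true):
        counts[index[t], index[p]] += 1
    row = counts.sum(1, keepdims=True)
    normalized = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    zero_rows = [labels[i] for i in np.flatnonzero(row[:, 0] == 0)]
    return ConfusionMatrix(labels, counts, normalized, zero_rows)


@dataclass
class ErrorPattern:
    """Fractions of misclassified windows assigned to an earlier vs later
    epoch, plus the named confusions of interest."""

    preceding: float
    subsequent: float
    delay_as_move: float
    free_as_move: float
    hold_as_free: float
    n_errors: int


def error_pattern(pred_epoch, true_epoch) -> ErrorPattern | None:
    """Directional error decomposition; ``None`` if nothing was misclassified."""
    pred = np.asarray(pred_epoch)
    true = np.asarray(true_epoch)
    p_rank = np.vectorize(EPOCH_RANK.get)(pred)
    t_rank = np.vectorize(EPOCH_RANK.get)(true)
    err = p_rank != t_rank
    n_err = int(err.sum())
    if n_err == 0:
        return None
    return ErrorPattern(
        preceding=float((p_rank[err] < t_rank[err]).mean()),
        subsequent=float((p_rank[err] > t_rank[err]).mean()),
        delay_as_move=float(((true == "DELAY") & (pred == "MOVE"))[err].sum() / n_err),
        free_as_move=float(((true == "FREE") & (pred == "MOVE"))[err].sum() / n_err),
        hold_as_free=float(((true == "HOLD") & (pred == "FREE"))[err].sum() / n_err),
        n_errors=n_err)


# ---------------------------------------------------------------------------
# target geometry and distance-confusion correlation
# ---------------------------------------------------------------------------

@dataclass
class TargetGeometry:
    """Workspace positions (cm) of the 9 targets and pairwise distances."""

    positions_cm: np.ndarray   # (9, 2)
    distances_cm: np.ndarray   # (9, 9)


def target_geometry() -> TargetGeometry:
    """The 3 x 3 (direction x depth) target grid at eye level: version angles
    -15/0/+15 degrees, radial distances 10/15/25 cm."""
    pos = target_positions_cm()
    diff = pos[:, None, :] - pos[None, :, :]
    return TargetGeometry(pos, np.sqrt((diff ** 2).sum(-1)))


def distance_confusion_correlation(conf: ConfusionMatrix,
                                   geom: TargetGeometry | None = None,
                                   method: str = "pearson"):
    """Correlation between symmetrized off-diagonal target confusion and
    physical target distance; returns ``(r, p)`` or ``None`` when all
    off-diagonal confusion is zero."""
    if geom is None:
        geom = target_geometry()
    C = conf.normalized
    if C.shape != (N_TARGETS, N_TARGETS):
        raise ValueError("expected a 9x9 target confusion matrix")
    iu = np.triu_indices(N_TARGETS, k=1)
    p_conf = ((C + C.T) / 2)[iu]
    if not p_conf.any():
        return None
    d = geom.distances_cm[iu]
    if np.ptp(p_conf) == 0:  # uniform confusion carries no distance signal
        return 0.0, 1.0
    if method == "pearson":
        r, p = stats.pearsonr(p_conf, d)
    elif method == "spearman":
        r, p = stats.spearmanr(p_conf, d)
    else:
        raise ValueError("method must be pearson or spearman")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Davies-Bouldin index
# ---------------------------------------------------------------------------

def r_metric(X, labels, i, j) -> float:
    """R value between clusters i and j: (S_i + S_j) / M_ij, with S the mean
    Euclidean distance to the centroid and M the centroid distance. Higher
    values mean more overlap; coincident centroids give infinity."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    s, m = {}, {}
    for k in (i, j):
        pts = X[labels == k]
        if len(pts) < 2:
            raise ValueError(f"cluster {k!r} needs >= 2 samples")
        m[k] = pts.mean(0)
        s[k] = float(np.linalg.norm(pts - m[k], axis=1).mean())
    sep = float(np.linalg.norm(m[i] - m[j]))
    if sep == 0:
        return np.inf
    return (s[i] + s[j]) / sep


def dbi(X, labels) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case R value."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters")
    worst = []
    for i in uniq:
        worst.append(max(r_metric(X, labels, i, j) for j in uniq if j != i))
    return float(np.mean(worst))


def bootstrap_dbi(X, labels, mode: str = "fraction", fraction: float = 0.9,
                  fixed_units: int = 40, n_boot: int = 1000,
                  seed: int = 0) -> np.ndarray:
    """DBI distribution under unit (feature-column) resampling.

    ``mode='fraction'`` keeps a random ``fraction`` of the units per sample
    (without replacement); ``mode='fixed'`` keeps exactly ``fixed_units``.
    Infinite values (coincident centroids) are excluded from summaries by
    the caller; a count is logged here.
    """
    X = np.asarray(X, float)
    n_units = X.shape[1]
    if mode == "fraction":
        keep = max(1, int(round(fraction * n_units)))
    elif mode == "fixed":
        keep = fixed_units
        if n_units < keep:
            raise ValueError(f"need >= {keep} units for fixed mode")
    else:
        raise ValueError("mode must be 'fraction' or 'fixed'")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.choice(n_units, keep, replace=False)
        out[b] = dbi(X[:, cols], labels)
    n_inf = int(np.isinf(out).sum())
    if n_inf:
        log.warning("bootstrap_dbi: %d infinite samples excluded from summaries", n_inf)
    return out


def epoch_rate_matrix(data: SpikeDataset, trials: TrialTable):
    """Mean firing rate of every unit in every (trial, epoch): the feature
    matrix of the exploratory clustering analyses.

    Returns ``(X, epoch_labels, target_labels, trial_ids)`` with X of shape
    (n_trials * 4, n_units) in sp/s.
    """
    n_rows = len(trials) * len(EPOCHS)
    X = np.zeros((n_rows, data.n_units))
    epoch_labels = np.empty(n_rows, object)
    target_labels = np.zeros(n_rows, int)
    trial_ids = np.zeros(n_rows, int)
    by_trial = dict(tuple(data.spikes.groupby("trial_id"))) if len(data.spikes) else {}
    r = 0
    for row in trials.df.itertuples(index=False):
        bounds = trials.epoch_bounds(row.trial_id)
        g = by_trial.get(row.trial_id)
        for e in EPOCHS:
            lo, hi = bounds[e]
            if g is not None:
                sel = g[(g["time_ms"] >= lo) & (g["time_ms"] < hi)]
                counts = np.bincount(sel["unit_id"].to_numpy() - 1,
                                     minlength=data.n_units)
                X[r] = counts / ((hi - lo) / 1000.0)
            epoch_labels[r] = e
            target_labels[r] = row.target_id
            trial_ids[r] = row.trial_id
            r += 1
    return X, epoch_labels, target_labels, trial_ids


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring; constant columns are left at zero."""
    X = np.asarray(X, float)
    mu = X.mean(0)
    sd = X.std(0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# perturbation loops
# ---------------------------------------------------------------------------

def shuffle_spike_noise(data: SpikeDataset, units, seed: int = 0) -> SpikeDataset:
    """Noise a subset of units: per (unit, trial), keep the first and last
    spikes and redraw the interior spike times uniformly between them (spike
    count preserved exactly). Units with fewer than 3 spikes in a trial are
    left unchanged."""
    units = set(int(u) for u in units)
    rng = np.random.default_rng(seed)
    sp = data.spikes.copy()
    times = sp["time_ms"].to_numpy().copy()
    for (uid, _tid), idx in sp.groupby(["unit_id", "trial_id"]).indices.items():
        if uid not in units or len(idx) < 3:
            continue
        t = times[idx]
        interior = np.round(rng.uniform(t[0], t[-1], len(idx) - 2), 1)
        times[idx] = np.concatenate([[t[0]], np.sort(interior), [t[-1]]])
    sp["time_ms"] = times
    return SpikeDataset(sp, data.n_units, data.trials, data.area)


def neuron_loss(n_units: int, eval_fn, ks=(2, 4, 8, 16, 32, 64),
                n_boot: int = 25, seed: int = 0) -> pd.DataFrame:
    """Neuron-dropping loop (models NOT retrained).

    ``eval_fn(removed_units) -> float | dict`` evaluates decoding accuracy
    with those units removed; ``k = 0`` is always evaluated once as the
    unperturbed reference. Levels with ``k >= n_units`` are skipped with a
    log message. Returns tidy rows (k, boot, accuracy...).
    """
    rng = np.random.default_rng(seed)
    rows = []

    def _record(k, b, res):
        res = {"accuracy": res} if np.isscalar(res) else dict(res)
        rows.append({"k": k, "boot": b, **res})

    _record(0, 0, eval_fn(np.array([], int)))
    for k in ks:
        if k >= n_units:
            log.info("neuron_loss: skipping k=%d >= population size %d", k, n_units)
            continue
        for b in range(n_boot):
            removed = rng.choice(n_units, k, replace=False) + 1
            _record(k, b, eval_fn(removed))
    return pd.DataFrame(rows)


def noise_injection(n_units: int, eval_fn, ks=(2, 4, 8, 16, 32, 64),
                    n_boot: int = 10, seed: int = 0) -> pd.DataFrame:
    """Spike-shuffle noise loop (models NOT retrained).

    ``eval_fn(noised_units, seed) -> float | dict``; the seed drives the
    interior-spike redraw. k = 0 is the clean reference.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def _record(k, b, res):
        res = {"accuracy": res} if np.isscalar(res) else dict(res)
        rows.append({"k": k, "boot": b, **res})

    _record(0, 0, eval_fn(np.array([], int), seed))
    for k in ks:
        if k > n_units:
            log.info("noise_injection: skipping k=%d > population size %d", k, n_units)
            continue
        for b in range(n_boot):
            noised = rng.choice(n_units, k, replace=False) + 1
            _record(k, b, eval_fn(noised, int(rng.integers(2 ** 31))))
    return pd.DataFrame(rows)


def subsample_curve(n_units: int, eval_fn, step: int = 5, n_repeats: int = 10,
                    seed: int = 0) -> tuple[pd.DataFrame, int | None]:
    """Accuracy versus population size, retraining per subset.

    ``eval_fn(units, seed) -> float | dict`` must train and evaluate on the
    given unit subset. Sizes run in ``step``-unit increments up to the full
    population (included). Also returns the minimum size whose mean accuracy
    exceeds 0.5 (None if never reached; uses the 'accuracy' column).
    """
    rng = np.random.default_rng(seed)
    sizes = list(range(step, n_units, step)) + [n_units]
    rows = []
    for size in sizes:
        reps = 1 if size == n_units else n_repeats
        for r in range(reps):
            units = rng.choice(n_units, size, replace=False) + 1
            res = eval_fn(units, int(rng.integers(2 ** 31)))
            res = {"accuracy": res} if np.isscalar(res) else dict(res)
            rows.append({"size": size, "repeat": r, **res})
    df = pd.DataFrame(rows)
    means = df.groupby("size")["accuracy"].mean()
    above = means[means > 0.5]
    return df, (int(above.index.min()) if len(above) else None)


# ---------------------------------------------------------------------------
# time course, statistics, embedding
# ---------------------------------------------------------------------------

def decode_timecourse(report: pd.DataFrame,
                      align_event: str = "movement_onset_ms") -> pd.DataFrame:
    """Target accuracy as a function of window position.

    Uses the windows of the movement-aligned segment only and excludes
    true-FREE windows, whose target label carries no spatial information.
    Rows: window midpoint (ms relative to movement onset), accuracy, n.
    """
    df = report[(report["event"] == align_event)
                & (report["true_epoch"] != "FREE")]
    mid = df["window_start_ms"] + df["width_ms"] / 2
    grouped = (df.assign(time_ms=mid, correct=df["pred_target"] == df["true_target"])
               .groupby("time_ms")["correct"])
    out = grouped.agg(["mean", "size"]).reset_index()
    return out.rename(columns={"mean": "accuracy", "size": "n"})


def compare_conditions(samples_a, samples_b, paired: bool = False) -> float:
    """Nonparametric rank test between two accuracy samples (p-value)."""
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if min(a.size, b.size) < 3:
        raise ValueError("need >= 3 samples per condition")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal sizes")
        if np.allclose(a, b):
            return 1.0
        return float(stats.wilcoxon(a, b).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def embed_2d(X, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Standardize and embed samples in 2-D with t-SNE (visualization only)."""
    from sklearn.manifold import TSNE

    Z = standardize(X)
    perplexity = min(perplexity, (len(Z) - 1) / 3)
    return TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca").fit_transform(Z)
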