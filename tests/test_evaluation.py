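"""Metrics and experiment loops against hand computations and oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reachstates import evaluation as ev
from reachstates.synthetic import make_population, make_task_schedule, simulate_spikes


class TestAccuracyAndChance:
    def test_perfect_prediction(self):
        acc, samples, thr = ev.accuracy_and_chance([1, 2, 3], [1, 2, 3],
                                                   n_shuffles=50, seed=0)
        assert acc == 1.0
        assert 0 <= thr <= 1

    def test_balanced_four_class_chance_quarter(self):
        rng = np.random.default_rng(1)
        true = np.repeat(np.arange(4), 500)
        pred = rng.permutation(true)
        _, samples, _ = ev.accuracy_and_chance(pred, true, n_shuffles=300, seed=2)
        # analytic permutation mean: sum of class proportions squared = 0.25
        assert samples.mean() == pytest.approx(0.25, abs=0.01)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            ev.accuracy_and_chance([], [])
        with pytest.raises(ValueError):
            ev.accuracy_and_chance([1], [1], n_shuffles=0)


class TestConfusion:
    def test_perfect_is_identity(self):
        cm = ev.confusion([0, 1, 2], [0, 1, 2], labels=[0, 1, 2])
        assert np.allclose(cm.normalized, np.eye(3))
        assert cm.n == 3

    def test_rows_sum_to_one_and_counts_conserved(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        cm = ev.confusion(pred, true, labels=range(4))
        assert cm.counts.sum() == 200
        assert np.allclose(cm.normalized.sum(1), 1)

    def test_absent_class_flagged_not_dropped(self):
        cm = ev.confusion([0, 0], [0, 0], labels=[0, 1])
        assert cm.zero_rows == [1]
        assert cm.counts.shape == (2, 2)


class TestErrorPattern:
    def test_all_below_diagonal(self):
        true = ["MOVE", "HOLD", "DELAY"]
        pred = ["DELAY", "FREE", "FREE"]
        ep = ev.error_pattern(pred, true)
        assert ep.preceding == 1.0 and ep.subsequent == 0.0
        assert ep.hold_as_free == pytest.approx(1 / 3)

    def test_symmetric_confusion_half_half(self):
        true = ["FREE", "DELAY"] * 10
        pred = ["DELAY", "FREE"] * 10
        ep = ev.error_pattern(pred, true)
        assert ep.preceding == 0.5 and ep.subsequent == 0.5

    def test_no_errors_reported_absent(self):
        assert ev.error_pattern(["MOVE"], ["MOVE"]) is None


class TestGeometry:
    def test_positions(self):
        geom = ev.target_geometry()
        assert np.allclose(geom.positions_cm[1], [0, 10])  # near central
        far_right = geom.positions_cm[8]
        assert far_right[0] == pytest.approx(25 * np.sin(np.deg2rad(15)))
        assert far_right[0] == pytest.approx(6.470, abs=1e-3)

    def test_mirror_symmetric_distances(self):
        geom = ev.target_geometry()
        d = geom.distances_cm
        # NL-IC equals NR-IC, etc.
        assert d[0, 4] == pytest.approx(d[2, 4])
        assert d[0, 3] == pytest.approx(d[2, 5])
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestDistanceConfusion:
    def _conf(self, C):
        C = np.asarray(C, float)
        row = C.sum(1, keepdims=True)
        row[row == 0] = 1
        return ev.ConfusionMatrix(list(range(9)), C, C / row, [])

    def test_exponential_decay_negative(self):
        geom = ev.target_geometry()
        C = np.exp(-geom.distances_cm)
        r, p = ev.distance_confusion_correlation(self._conf(C), geom)
        assert r < -0.5

    def test_uniform_confusion_zero(self):
        C = np.full((9, 9), 0.1)
        r, _ = ev.distance_confusion_correlation(self._conf(C))
        assert abs(r) < 1e-9

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(3)
        geom = ev.target_geometry()
        C = np.exp(-geom.distances_cm)
        rs = []
        for _ in range(30):
            perm = rng.permutation(9)
            r, _ = ev.distance_confusion_correlation(self._conf(C[np.ix_(perm, perm)]), geom)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.2

    def test_all_zero_off_diagonal_absent(self):
        assert ev.distance_confusion_correlation(self._conf(np.eye(9))) is None


class TestDBI:
    def test_hand_computed_two_cluster(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([0, 0, 1, 1])
        # S = 1 each, M = 10 -> R = 0.2 -> DBI = 0.2
        assert ev.dbi(X, labels) == pytest.approx(0.2)
        assert ev.r_metric(X, labels, 0, 1) == pytest.approx(0.2)

    def test_zero_scatter_clusters(self):
        X = np.array([[0, 0], [0, 0], [3, 4], [3, 4]], float)
        assert ev.dbi(X, [0, 0, 1, 1]) == 0.0

    def test_coincident_centroids_infinite(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        assert np.isinf(ev.r_metric(X, [0, 0, 1, 1], 0, 1))

    def test_exhaustive_small_instances_match_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 7)
            X = rng.normal(size=(n, 1))
            labels = np.array([0, 0] + list(rng.integers(0, 2, n - 4)) + [1, 1])
            pts = {k: X[labels == k] for k in (0, 1)}
            s = {k: np.abs(p - p.mean()).mean() for k, p in pts.items()}
            m = abs(pts[0].mean() - pts[1].mean())
            expect = (s[0] + s[1]) / m
            assert ev.dbi(X, labels) == pytest.approx(expect)

    def test_matches_sklearn(self):
        from sklearn.metrics import davies_bouldin_score
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4)) + np.repeat(np.arange(3), 20)[:, None]
        labels = np.repeat(np.arange(3), 20)
        assert ev.dbi(X, labels) == pytest.approx(davies_bouldin_score(X, labels))

    def test_merging_clusters_increases_dbi(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(5, 0.5, (30, 2)),
                       rng.normal([0, 5], 0.5, (30, 2))])
        good = np.repeat([0, 1, 2], 30)
        base = ev.dbi(X, good)
        merged = good.copy()
        merged[rng.permutation(np.flatnonzero(good == 2))[:15]] = 0
        merged[merged == 2] = 1
        assert ev.dbi(X, merged) > base


class TestBootstrapDBI:
    def _data(self, n_units=45, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, n_units)) + np.repeat([0, 2], 40)[:, None]
        return X, np.repeat([0, 1], 40)

    def test_full_fraction_single_boot_equals_plain(self):
        X, labels = self._data()
        out = ev.bootstrap_dbi(X, labels, mode="fraction", fraction=1.0,
                               n_boot=1, seed=0)
        assert out[0] == pytest.approx(ev.dbi(X, labels))

    def test_fixed_mode_subset_size(self):
        X, labels = self._data(42)
        out = ev.bootstrap_dbi(X, labels, mode="fixed", fixed_units=40,
                               n_boot=20, seed=1)
        assert len(out) == 20 and np.isfinite(out).all()
        with pytest.raises(ValueError, match="units"):
            ev.bootstrap_dbi(X[:, :30], labels, mode="fixed", fixed_units=40)

    def test_spread_shrinks_with_population_size(self):
        big, labels = self._data(120, seed=2)
        small = big[:, :30]
        sd_small = ev.bootstrap_dbi(small, labels, n_boot=60, seed=3).std()
        sd_big = ev.bootstrap_dbi(big, labels, n_boot=60, seed=3).std()
        assert sd_big < sd_small


class TestPerturbationLoops:
    def test_neuron_loss_reference_and_skip(self, caplog):
        calls = []

        def fn(removed):
            calls.append(tuple(sorted(removed)))
            return 1.0 - 0.01 * len(removed)

        df = ev.neuron_loss(10, fn, ks=(2, 4, 64), n_boot=3, seed=0)
        assert (df.loc[df.k == 0, "accuracy"] == 1.0).all()
        assert set(df.k) == {0, 2, 4}  # 64 skipped
        assert len(df) == 1 + 2 * 3

    def test_noise_conservation(self, small_session):
        _, trials, data = small_session
        noised = ev.shuffle_spike_noise(data, units=[1, 2, 3], seed=4)
        a = data.spikes.groupby(["unit_id", "trial_id"])["time_ms"]
        b = noised.spikes.groupby(["unit_id", "trial_id"])["time_ms"]
        assert (a.size() == b.size()).all()  # spike counts preserved
        for key in list(a.groups)[:40]:
            ta, tb = a.get_group(key).to_numpy(), np.sort(b.get_group(key).to_numpy())
            assert ta[0] == tb[0] and ta[-1] == tb[-1]
            if key[0] not in (1, 2, 3) or len(ta) < 3:
                assert np.array_equal(np.sort(ta), tb)

    def test_subsample_sizes_and_threshold(self):
        def fn(units, seed):
            return min(1.0, len(units) / 20)

        df, min_units = ev.subsample_curve(23, fn, step=5, n_repeats=2, seed=0)
        assert sorted(df["size"].unique()) == [5, 10, 15, 20, 23]
        assert (df.loc[df["size"] == 23, "repeat"] == 0).all()
        assert min_units == 15  # first mean accuracy > 0.5


class TestStatsAndEmbedding:
    def test_identical_samples_p_one(self):
        a = np.arange(10.0)
        assert ev.compare_conditions(a, a.copy(), paired=True) == 1.0
        assert ev.compare_conditions(a, a.copy()) > 0.9

    def test_disjoint_support_significant(self):
        a = np.arange(20.0)
        b = a + 100
        assert ev.compare_conditions(a, b) < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ev.compare_conditions([1, 2], [1, 2])

    def test_embedding_shape_determinism_separation(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (40, 8)), rng.normal(4, 0.3, (40, 8))])
        labels = np.repeat([0, 1], 40)
        a = ev.embed_2d(X, perplexity=10, seed=1)
        b = ev.embed_2d(X, perplexity=10, seed=1)
        assert a.shape == (80, 2)
        assert np.allclose(a, b)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(a, labels) > 0


def test_epoch_rate_matrix_shapes(small_session):
    _, trials, data = small_session
    X, epochs, targets, tids = ev.epoch_rate_matrix(data, trials)
    assert X.shape == (len(trials) * 4, data.n_units)
    assert set(epochs) == {"FREE", "DELAY", "MOVE", "HOLD"}
    assert (X >= 0).all()
    # spot check one (trial, epoch) cell
    tid = trials.trial_ids[3]
    lo, hi = trials.epoch_bounds(tid)["MOVE"]
    g = data.spikes
    manual = ((g.trial_id == tid) & (g.unit_id == 2)
              & (g.time_ms >= lo) & (g.time_ms < hi)).sum() / ((hi - lo) / 1000)
    row = np.flatnonzero((tids == tid) & (epochs == "MOVE"))[0]
    assert X[row, 1] == pytest.approx(manual)


def test_free_hold_overlap_larger_in_pe_like():
    """The PE-like preset's FREE/HOLD population similarity shows up as a
    larger R value between those epoch clusters than in V6A-like data."""
    r_pe, r_v6a = [], []
    for seed in range(10):
        for profile, acc in (("PE-like", r_pe), ("V6A-like", r_v6a)):
            spec = make_population(25, profile, seed=seed)
            trials = make_task_schedule(3, seed=seed + 50)
            data = simulate_spikes(spec, trials, seed=seed + 90)
            X, epochs, _, _ = ev.epoch_rate_matrix(data, trials)
            Z = ev.standardize(X)
            sel = np.isin(epochs, ["FREE", "HOLD"])
            acc.append(ev.r_metric(Z[sel], epochs[sel], "FREE", "HOLD"))
    assert np.mean(r_pe) > np.mean(r_v6a)
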