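"""SVM and LSTM reference classifiers over the same 28 (epoch, target) classes.

Both operate on 200-ms sliding windows (10-ms step by default): the SVM on
per-unit mean firing rates, the LSTM on the raw 2-ms binned counts. The SVM
is scikit-learn's SVC (one-vs-one multiclass) with the grid of C values and
kernels used for model selection; the LSTM is a compact numpy implementation
(LSTM layer -> dropout -> fully connected -> softmax) trained with Adam and
backpropagation through time, retaining the weights with the lowest
validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .preprocessing import BinnedCounts

#: C values and kernels scanned by the SVM grid search
SVM_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
SVM_POLY_DEGREES = tuple(range(2, 9))


@dataclass
class WindowFeatures:
    """Per-window features plus the metadata needed to label them."""

    meta: pd.DataFrame          # trial_id, event, window_start_ms, width_ms
    rates: np.ndarray           # (n_windows, n_units) sp/s
    binned: np.ndarray | None   # (n_windows, n_bins, n_units) counts


def window_features(segments: list[BinnedCounts], width_ms: float,
                    step_ms: float = 10.0,
                    keep_binned: bool = True) -> WindowFeatures:
    """Cut sliding windows out of aligned binned counts.

    Windows are laid within each segment (so they cannot straddle the seam
    between the pre-cue and movement-centred stretches) and produce both the
    mean firing rate per unit (count / window length) and, optionally, the
    raw bin-resolved counts for the LSTM.
    """
    metas, rate_parts, bin_parts = [], [], []
    for seg in segments:
        width_b = width_ms / seg.bin_ms
        step_b = step_ms / seg.bin_ms
        if abs(width_b - round(width_b)) > 1e-9 or abs(step_b - round(step_b)) > 1e-9:
            raise ValueError("width/step must be multiples of bin_ms")
        width_b, step_b = int(round(width_b)), int(round(step_b))
        for start in range(0, seg.n_bins - width_b + 1, step_b):
            sl = seg.counts[:, :, start:start + width_b]  # trials x units x bins
            rate_parts.append(sl.sum(axis=2) / (width_ms / 1000.0))
            if keep_binned:
                bin_parts.append(sl.transpose(0, 2, 1).astype(np.int8))
            metas.append(pd.DataFrame({
                "trial_id": seg.trial_ids,
                "event": seg.event,
                "window_start_ms": seg.window_ms[0] + start * seg.bin_ms,
                "width_ms": float(width_ms),
            }))
    return WindowFeatures(
        pd.concat(metas, ignore_index=True),
        np.concatenate(rate_parts, axis=0),
        np.concatenate(bin_parts, axis=0) if keep_binned else None)


def zero_units(X: np.ndarray, units, axis: int = -1) -> np.ndarray:
    """Removed-unit convention: feature rates / input rows set to 0."""
    out = X.copy()
    idx = np.asarray([u - 1 for u in units], int)
    out_swapped = np.swapaxes(out, axis, -1)
    out_swapped[..., idx] = 0
    return out


def svm_fit(X, y, grid: dict | None = None, cv: int = 3, seed: int = 0):
    """Grid-searched multiclass SVC.

    The default grid scans the 7 C values against an RBF kernel (automatic
    width) and polynomial kernels of degree 2-8, by cross-validated
    accuracy. Returns the refitted best classifier and a metadata dict;
    multiclass reduction is one-vs-one (SVC's native scheme).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if grid is None:
        grid = [
            {"kernel": ["rbf"], "gamma": ["scale"], "C": list(SVM_C_GRID)},
            {"kernel": ["poly"], "degree": list(SVM_POLY_DEGREES),
             "C": list(SVM_C_GRID)},
        ]
    search = GridSearchCV(SVC(random_state=seed), grid, cv=cv,
                          scoring="accuracy", n_jobs=None)
    search.fit(X, y)
    info = {"best_params": search.best_params_,
            "cv_accuracy": float(search.best_score_),
            "multiclass": "one-vs-one"}
    return search.best_estimator_, info


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTMClassifier:
    """Minimal LSTM sequence classifier in numpy.

    Architecture: one LSTM layer over the input sequence, dropout on the
    final hidden state, a fully connected layer of size ``n_classes`` and a
    softmax; prediction is winner-takes-all. Trained by Adam on minibatches
    with full backpropagation through time.
    """

    def __init__(self, n_inputs: int, n_classes: int, hidden: int = 200,
                 dropout: float = 0.1, seed: int = 0):
        self.n_inputs, self.n_classes, self.hidden = n_inputs, n_classes, hidden
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        H, D, C = hidden, n_inputs, n_classes
        s_x, s_h, s_d = (1 / np.sqrt(D), 1 / np.sqrt(H), 1 / np.sqrt(H))
        self.params = {
            "Wx": rng.uniform(-s_x, s_x, (4 * H, D)),
            "Wh": rng.uniform(-s_h, s_h, (4 * H, H)),
            "b": np.zeros(4 * H),
            "Wd": rng.uniform(-s_d, s_d, (C, H)),
            "bd": np.zeros(C),
        }
        self.params["b"][H:2 * H] = 1.0  # forget-gate bias
        self._rng = rng
        self.history_: list[tuple[int, float]] = []

    # -- forward ---------------------------------------------------------
    def _forward(self, X, train: bool = False):
        B, T, _ = X.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if train else None
        for t in range(T):
            z = X[:, t] @ Wx.T + h @ Wh.T + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if train:
                cache.append((X[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h, cache

    def _logits(self, h):
        return h @ self.params["Wd"].T + self.params["bd"]

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, X, y) -> float:
        h, _ = self._forward(X)
        p = self._softmax(self._logits(h))
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))

    def predict(self, X) -> np.ndarray:
        h, _ = self._forward(np.asarray(X, float))
        return np.argmax(self._logits(h), axis=1)

    # -- training --------------------------------------------------------
    def _backward(self, cache, dh):
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()
                 if k in ("Wx", "Wh", "b")}
        dc = np.zeros_like(dh)
        for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(cache):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            grads["Wx"] += dz.T @ x_t
            grads["Wh"] += dz.T @ h_prev
            grads["b"] += dz.sum(axis=0)
            dh = dz @ Wh
            dc = dc * f
        return grads

    def fit(self, X, y, X_val=None, y_val=None, lr: float = 1e-2,
            batch_size: int = 1024, n_iters: int = 300, eval_every: int = 10,
            clip: float = 5.0):
        """Adam training; retains the weights with the lowest validation
        loss (training loss if no validation set is given)."""
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        n = len(y)
        batch_size = min(batch_size, n)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        best = {k: p.copy() for k, p in self.params.items()}
        best_loss = np.inf
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for it in range(1, n_iters + 1):
            idx = self._rng.choice(n, batch_size, replace=False)
            xb, yb = X[idx], y[idx]
            h, cache = self._forward(xb, train=True)
            if self.dropout > 0:
                mask = (self._rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
            else:
                mask = np.ones_like(h)
            hd = h * mask
            p = self._softmax(self._logits(hd))
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = {"Wd": dlogits.T @ hd, "bd": dlogits.sum(axis=0)}
            dh = (dlogits @ self.params["Wd"]) * mask
            grads.update(self._backward(cache, dh))
            norm = np.sqrt(sum((g ** 2).sum() for g in grads.values()))
            if norm > clip:
                grads = {k: g * (clip / norm) for k, g in grads.items()}
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g ** 2
                mh = m[k] / (1 - beta1 ** it)
                vh = v[k] / (1 - beta2 ** it)
                self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
            if it % eval_every == 0 or it == n_iters:
                val = (self.loss(X_val, y_val) if X_val is not None
                       else self.loss(X[idx], y[idx]))
                self.history_.append((it, val))
                if val < best_loss:
                    best_loss = val
                    best = {k: p_.copy() for k, p_ in self.params.items()}
        self.params = best
        self.best_loss_ = best_loss
        return self


def lstm_fit(X, y, X_val=None, y_val=None, n_classes: int | None = None,
             hidden: int = 200, dropout: float = 0.1, lr: float = 1e-2,
             batch_size: int = 1024, n_iters: int = 300, seed: int = 0,
             expected_classes=None) -> LSTMClassifier:
    """Train the LSTM baseline on (windows x bins x units) count arrays.

    Defaults: hidden 200, learning rate 1e-2, minibatch 1,024 (automatically
    reduced when the training set is smaller), dropout 0.1. If
    ``expected_classes`` is given, every one of those class ids must occur
    in the training labels.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if expected_classes is not None:
        missing = set(int(c) for c in expected_classes) - set(y.tolist())
        if missing:
            raise ValueError(
                f"classes missing from training fold: {sorted(missing)[:5]}")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    clf = LSTMClassifier(X.shape[2], n_classes, hidden=hidden,
                         dropout=dropout, seed=seed)
    return clf.fit(X, y, X_val, y_val, lr=lr, batch_size=batch_size,
                   n_iters=n_iters)


def predict(classifier, X) -> np.ndarray:
    """Uniform prediction entry point for either baseline."""
    X = np.asarray(X, float)
    if isinstance(classifier, LSTMClassifier):
        if X.shape[2] != classifier.n_inputs:
            raise ValueError("feature-length mismatch")
        return classifier.predict(X)
    if X.shape[1] != classifier.n_features_in_:
        raise ValueError("feature-length mismatch")
    return classifier.predict(X)
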