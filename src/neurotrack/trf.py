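"""Boosted temporal response functions (TRFs) with cross-validation.

A TRF is a linear kernel ``h[p, l, c]`` mapping speech feature ``p`` at lag
``l`` (spanning -100..600 ms, 89 samples at 128 Hz) to EEG channel ``c``:

    pred[c, t] = sum_p sum_l h[p, l, c] * x_p[t - l]

Kernels are estimated by greedy coordinate-descent boosting: starting from
zero, each iteration applies the single +-delta update over (predictor, lag)
that most reduces the training squared error, with early stopping on the
l2-norm of the validation residual.  A 50 ms Hamming basis window makes the
kernels less sparse; by default it is applied in the fitting loop (the
candidate updates are smoothed bumps rather than deltas).

Everything runs in sufficient-statistic space: per-segment Gram matrices of
the lagged design and feature-EEG cross-covariances, so the expensive parts
are shared across folds, channels and (for a fixed stimulus) subjects.
Segment boundaries are treated as zero-padded, i.e. lagged values that would
cross a fold boundary are zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import EEGRecording, FeatureSet

__all__ = [
    "lag_samples",
    "lagged_design",
    "basis_matrix",
    "smooth_basis",
    "predict_eeg",
    "prediction_accuracy",
    "FoldSplit",
    "make_folds",
    "DesignStats",
    "BoostingTRF",
    "TRFModel",
    "crossval_trf",
]


def lag_samples(fs: float, tmin: float = -0.1, tmax: float = 0.6) -> np.ndarray:
    """Integer lags (samples) inside [tmin, tmax] seconds at ``fs``.

    Fractional endpoints truncate toward zero, so the default -100..600 ms
    window at 128 Hz gives lags -12..76 (89 samples).
    """
    return np.arange(int(np.trunc(tmin * fs)), int(np.trunc(tmax * fs)) + 1)


def lagged_design(X: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time x (predictor, lag) design matrix with zero padding.

    ``X`` is (P, T); column ``(p, l)`` of the result holds ``x_p[t - l]``
    (zero where ``t - l`` falls outside the segment).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P, T = X.shape
    L = len(lags)
    D = np.zeros((T, P * L))
    for p in range(P):
        for j, lag in enumerate(lags):
            if abs(lag) >= T:
                continue
            col = D[:, p * L + j]
            if lag >= 0:
                col[lag:] = X[p, : T - lag] if lag else X[p]
            else:
                col[:lag] = X[p, -lag:]
    return D


def basis_matrix(n_lags: int, fs: float, window_s: float = 0.05) -> np.ndarray:
    """Column-stochastic smoothing matrix for one predictor's lag axis.

    Column ``j`` is a unit-area Hamming window of ``round(window_s * fs)``
    samples centered on lag ``j``, truncated at the window edges and
    renormalized so every coefficient's mass stays inside the lag axis
    (kernel mass is preserved exactly).
    """
    m = max(1, int(round(window_s * fs)))
    if m > n_lags:
        raise ValueError(f"basis window ({m} samples) longer than lag axis ({n_lags})")
    w = np.hamming(m)
    w = w / w.sum()
    S = np.zeros((n_lags, n_lags))
    half = (m - 1) // 2
    for j in range(n_lags):
        for i, wi in enumerate(w):
            lag = j + i - half
            if 0 <= lag < n_lags:
                S[lag, j] += wi
        S[:, j] /= S[:, j].sum()
    return S


def smooth_basis(kernels: np.ndarray, fs: float, window_s: float = 0.05) -> np.ndarray:
    """Convolve the lag axis of ``(P, L, ...)`` kernels with the basis window."""
    kernels = np.asarray(kernels, dtype=float)
    S = basis_matrix(kernels.shape[1], fs, window_s)
    return np.einsum("lj,pj...->pl...", S, kernels)


def predict_eeg(kernels: np.ndarray, X: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Predicted EEG ``(C, T)`` from kernels ``(P, L, C)`` and features ``(P, T)``.

    Honors the acausal part of the lag axis: a feature sample at time t
    influences the prediction from ``t + lags[0]`` to ``t + lags[-1]``.
    """
    kernels = np.asarray(kernels, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P, L, C = kernels.shape
    if X.shape[0] != P:
        raise ValueError(f"{X.shape[0]} feature rows for {P} kernel predictors")
    T = X.shape[1]
    D = lagged_design(X, lags)  # (T, P*L)
    return (D @ kernels.reshape(P * L, C)).T


def prediction_accuracy(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-channel Pearson correlation between predicted and measured EEG."""
    pred = np.atleast_2d(pred)
    actual = np.atleast_2d(actual)
    if pred.shape != actual.shape:
        raise ValueError("shape mismatch between prediction and measurement")
    if pred.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    p = pred - pred.mean(axis=1, keepdims=True)
    a = actual - actual.mean(axis=1, keepdims=True)
    sp = np.sqrt((p * p).sum(axis=1))
    sa = np.sqrt((a * a).sum(axis=1))
    if np.any(sp == 0) or np.any(sa == 0):
        raise ValueError("zero-variance input: correlation undefined")
    return (p * a).sum(axis=1) / (sp * sa)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k contiguous segments partitioning [0, T) plus the role rotation."""

    segments: list[slice]
    n_samples: int

    @property
    def k(self) -> int:
        return len(self.segments)

    def rotations(self):
        """Yield (train_segment_ids, val_id, test_id) for every rotation."""
        k = self.k
        for test in range(k):
            val = (test + 1) % k
            train = [i for i in range(k) if i not in (test, val)]
            yield train, val, test


def make_folds(T: int, k: int = 10) -> FoldSplit:
    """Split [0, T) into k contiguous segments with lengths differing <= 1.

    The remainder ``T % k`` is absorbed by the first segments.
    """
    if T < k:
        raise ValueError(f"cannot make {k} folds from {T} samples")
    base, rem = divmod(T, k)
    segments, start = [], 0
    for i in range(k):
        length = base + (1 if i < rem else 0)
        segments.append(slice(start, start + length))
        start += length
    return FoldSplit(segments=segments, n_samples=T)


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

class DesignStats:
    """Per-segment Gram matrices and cross-covariances of a lagged design.

    Computing these once per stimulus lets every subject sharing that
    stimulus reuse the Grams; nested models reuse sub-blocks via
    :meth:`subset`.
    """

    def __init__(self, X: np.ndarray, lags: np.ndarray, folds: FoldSplit):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.X = X
        self.lags = np.asarray(lags)
        self.folds = folds
        self.P, self.T = X.shape
        self.L = len(lags)
        if folds.n_samples != self.T:
            raise ValueError("fold split does not match design length")
        self.grams = []
        self._design_cache: dict[int, np.ndarray] = {}
        self._parent = None
        self._col_idx = None
        for i, seg in enumerate(folds.segments):
            D = lagged_design(X[:, seg], lags)
            self.grams.append(D.T @ D)
            self._design_cache[i] = D.astype(np.float32)

    def lagged(self, seg_id: int) -> np.ndarray:
        """Cached (T_seg, P*L) lagged design of one segment (float32)."""
        if self._parent is not None:
            return self._parent.lagged(seg_id)[:, self._col_idx]
        return self._design_cache[seg_id]

    def crosscov(self, y: np.ndarray) -> list[np.ndarray]:
        """Per-segment ``(P*L, C)`` cross-covariance with EEG ``y`` (C, T)."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != self.T:
            raise ValueError("EEG length does not match design")
        out = []
        for seg in self.folds.segments:
            xs = self.X[:, seg]
            ys = y[:, seg]
            n = xs.shape[1]
            # b[(p,l),c] = sum_t x_p[t-l] y_c[t]  == cross-correlation at lag l
            size = int(2 ** np.ceil(np.log2(2 * n)))
            fx = np.fft.rfft(xs, size)
            fy = np.fft.rfft(ys, size)
            b = np.empty((self.P, self.L, y.shape[0]))
            for p in range(self.P):
                # ifft(conj(fx) * fy)[d] = sum_t x[t] y[t+d]; lag l lives at
                # index l (l >= 0) or size + l (l < 0)
                cc = np.fft.irfft(np.conj(fx[p])[None, :] * fy, size)
                for j, lag in enumerate(self.lags):
                    b[p, j, :] = cc[:, lag] if lag >= 0 else cc[:, size + lag]
            out.append(b.reshape(self.P * self.L, y.shape[0]))
        return out

    def sq_norms(self, y: np.ndarray) -> list[np.ndarray]:
        """Per-segment per-channel sum of squares of ``y``."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return [(y[:, seg] ** 2).sum(axis=1) for seg in self.folds.segments]

    def subset(self, predictor_ids) -> "DesignStats":
        """View restricted to a subset of predictor rows (for nested models)."""
        predictor_ids = list(predictor_ids)
        idx = np.concatenate(
            [np.arange(p * self.L, (p + 1) * self.L) for p in predictor_ids]
        )
        sub = object.__new__(DesignStats)
        sub.X = self.X[predictor_ids]
        sub.lags = self.lags
        sub.folds = self.folds
        sub.P = len(predictor_ids)
        sub.T = self.T
        sub.L = self.L
        sub.grams = [g[np.ix_(idx, idx)] for g in self.grams]
        sub._design_cache = {}
        sub._parent = self
        sub._col_idx = idx
        return sub


# ---------------------------------------------------------------------------
# Boosting estimator
# ---------------------------------------------------------------------------

class BoostingTRF(BaseEstimator, RegressorMixin):
    """Greedy boosting estimator for multivariate TRFs.

    Follows the scikit-learn estimator contract: ``fit(X, y)`` with ``X`` of
    shape (n_samples, n_predictors) and ``y`` (n_samples, n_channels);
    fitted kernels land in ``kernels_`` with shape
    (n_predictors, n_lags, n_channels).

    Parameters
    ----------
    fs : sampling rate of both features and EEG (Hz).
    tmin, tmax : lag window in seconds (default -0.1..0.6).
    delta : boosting step as a fraction of each EEG channel's SD.
    patience : number of consecutive validation evaluations without
        improvement before a channel stops.
    max_iter : hard iteration cap.
    basis : Hamming basis window length in seconds (0 disables smoothing).
    basis_mode : 'in_loop' smooths the candidate updates during fitting;
        'post' smooths the final kernel only.
    scale_features : divide each predictor by its training SD before
        fitting (inverted on the returned kernels) so ``delta`` is
        comparable across dense and sparse predictors.
    stopping : 'per_channel' lets channels converge independently;
        'global' stops all channels on the summed validation error.
    validation_fraction : tail fraction held out when ``fit`` is called
        without an explicit validation set.
    """

    def __init__(self, fs: float = 128.0, tmin: float = -0.1, tmax: float = 0.6,
                 delta: float = 0.005, patience: int = 10, max_iter: int = 10000,
                 basis: float = 0.05, basis_mode: str = "in_loop",
                 scale_features: bool = True, stopping: str = "per_channel",
                 validation_fraction: float = 0.1):
        self.fs = fs
        self.tmin = tmin
        self.tmax = tmax
        self.delta = delta
        self.patience = patience
        self.max_iter = max_iter
        self.basis = basis
        self.basis_mode = basis_mode
        self.scale_features = scale_features
        self.stopping = stopping
        self.validation_fraction = validation_fraction

    # -- public API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit kernels on (X, y), early-stopping on a validation set.

        Without an explicit validation set the trailing
        ``validation_fraction`` of the data is held out.
        """
        X, y = self._check_Xy(X, y)
        if self.basis_mode not in ("in_loop", "post"):
            raise ValueError("basis_mode must be 'in_loop' or 'post'")
        if (X_val is None) != (y_val is None):
            raise ValueError("provide both X_val and y_val or neither")
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * X.shape[1])))
            X, X_val = X[:, :-n_val], X[:, -n_val:]
            y, y_val = y[:, :-n_val], y[:, -n_val:]
        else:
            X_val, y_val = self._check_Xy(X_val, y_val)

        lags = lag_samples(self.fs, self.tmin, self.tmax)
        Dtr = lagged_design(X, lags)
        Dva = lagged_design(X_val, lags)
        stats = {
            "G_train": Dtr.T @ Dtr,
            "b_train": Dtr.T @ y.T,
            "G_val": Dva.T @ Dva,
            "b_val": Dva.T @ y_val.T,
            "yy_val": (y_val ** 2).sum(axis=1),
        }
        sd_x = X.std(axis=1)
        sd_y = y.std(axis=1)
        kernels, n_iter = self._fit_from_stats(stats, sd_x, sd_y, len(lags))
        self.lags_ = lags
        self.kernels_ = kernels
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[0]
        return self

    def predict(self, X):
        """Predicted EEG, shape (n_samples, n_channels)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.kernels_.shape[0]:
            X = X.T
        return predict_eeg(self.kernels_, X, self.lags_).T

    def score(self, X, y):
        """Mean per-channel Pearson r between prediction and ``y``."""
        pred = self.predict(X)
        y = np.asarray(y, dtype=float)
        if y.shape != pred.shape:
            y = y.T
        return float(prediction_accuracy(pred.T, y.T).mean())

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _check_Xy(X, y):
        """Return (P, T) features and (C, T) EEG from sklearn-shaped input."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if X.shape[0] == y.shape[0] and X.shape[0] != X.shape[1]:
            # (n_samples, P) / (n_samples, C) orientation
            X, y = X.T, y.T
        if X.shape[1] != y.shape[1]:
            raise ValueError(
                f"features ({X.shape}) and EEG ({y.shape}) must share the time axis"
            )
        return X, y

    def _fit_from_stats(self, stats, sd_x, sd_y, L):
        """Boosting in coefficient space from precomputed sufficient stats."""
        G_train = stats["G_train"]
        b_train = stats["b_train"]
        G_val = stats["G_val"]
        b_val = stats["b_val"]
        yy_val = np.asarray(stats["yy_val"], dtype=float)
        P = G_train.shape[0] // L
        C = b_train.shape[1]

        # feature scaling: x~ = x / sd  <=>  G~ = D G D, b~ = D b
        if self.scale_features:
            sd_x = np.where(sd_x > 0, sd_x, 1.0)
            d = np.repeat(1.0 / sd_x, L)
        else:
            d = np.ones(P * L)
        # basis smoothing in-loop: design columns become smoothed bumps
        if self.basis and self.basis_mode == "in_loop":
            S1 = basis_matrix(L, self.fs, self.basis)
            S = np.kron(np.eye(P), S1)
            M = S * d[:, None]  # combined coefficient -> raw kernel map
        else:
            M = np.diag(d)
        G_train = M.T @ G_train @ M
        b_train = M.T @ b_train
        G_val = M.T @ G_val @ M
        b_val = M.T @ b_val

        delta_c = self.delta * sd_y
        dead = delta_c == 0
        if dead.any():
            warnings.warn("constant EEG channel(s): zero kernels returned")

        coef = self._boost(G_train, b_train, G_val, b_val, yy_val, delta_c)
        kernels = (M @ coef.T).T.reshape(C, P, L).transpose(1, 2, 0)
        if self.basis and self.basis_mode == "post":
            kernels = smooth_basis(kernels, self.fs, self.basis)
        return kernels, self._last_n_iter

    def _boost(self, G, b, Gv, bv, yy_val, delta_c):
        """Vectorized-over-channels greedy coordinate descent.

        Maintains R = b - G h (training residual correlations) and
        V = bv - Gv h; the validation SSE is updated incrementally.
        Returns the coefficients at each channel's validation optimum.
        """
        J = G.shape[0]
        C = b.shape[1]
        Gd = np.diag(G).copy()
        Gvd = np.diag(Gv).copy()
        h = np.zeros((C, J))
        best_h = np.zeros((C, J))
        R = b.T.copy()
        V = bv.T.copy()
        sse_val = yy_val.astype(float).copy()
        best_sse = sse_val.copy()
        bad = np.zeros(C, dtype=int)
        active = delta_c > 0
        glob = self.stopping == "global"
        it = 0
        while active.any() and it < self.max_iter:
            it += 1
            sub = np.nonzero(active)[0]
            dc = delta_c[sub]
            gains = 2.0 * dc[:, None] * np.abs(R[sub]) - (dc ** 2)[:, None] * Gd[None, :]
            j = np.argmax(gains, axis=1)
            g = gains[np.arange(len(sub)), j]
            # a channel with no error-reducing step is finished
            stop_now = g <= 0
            if stop_now.any():
                active[sub[stop_now]] = False
                keep = ~stop_now
                sub, j, dc = sub[keep], j[keep], dc[keep]
                if sub.size == 0:
                    continue
            step = np.sign(R[sub, j]) * dc
            h[sub, j] += step
            R[sub] -= step[:, None] * G[j]
            sse_val[sub] -= 2.0 * step * V[sub, j] - (dc ** 2) * Gvd[j]
            V[sub] -= step[:, None] * Gv[j]
            if glob:
                tot = sse_val.sum()
                if tot < best_sse.sum() - 1e-15:
                    best_h[:] = h
                    best_sse[:] = sse_val
                    bad[:] = 0
                else:
                    bad += 1
                    if bad[0] > self.patience:
                        active[:] = False
            else:
                improved = sse_val[sub] < best_sse[sub]
                imp = sub[improved]
                best_h[imp] = h[imp]
                best_sse[imp] = sse_val[imp]
                bad[imp] = 0
                worse = sub[~improved]
                bad[worse] += 1
                active[worse[bad[worse] > self.patience]] = False
        self._last_n_iter = it
        return best_h


# ---------------------------------------------------------------------------
# Cross-validated TRF
# ---------------------------------------------------------------------------

@dataclass
class TRFModel:
    """Cross-validated TRF: fold-averaged kernels and test accuracies."""

    kernels: np.ndarray            # (P, L, C), mean over folds
    lags: np.ndarray               # samples
    fs: float
    predictor_names: list[str]
    fold_accuracies: np.ndarray    # (k, C) Pearson r on test segments
    channel_labels: tuple[str, ...] = ()

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags / self.fs * 1000.0

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=0)


def crossval_trf(
    features,
    eeg,
    feature_names=None,
    k: int = 10,
    stats: DesignStats | None = None,
    crosscov=None,
    sq_norms=None,
    **params,
) -> TRFModel:
    """Estimate a TRF under k-fold cross-validation.

    ``features`` may be a FeatureSet (with ``feature_names`` selecting and
    expanding multi-band features) or a (P, T) array.  ``eeg`` may be an
    EEGRecording or a (C, T) array.  Each rotation trains on k-2 contiguous
    segments, early-stops on one validation segment and scores on one test
    segment; test segments tile the recording exactly once.  ``stats``
    allows reusing precomputed :class:`DesignStats` for the same stimulus.
    """
    if isinstance(features, FeatureSet):
        X, labels = features.design_matrix(feature_names)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        labels = list(feature_names) if feature_names else [
            f"x{i}" for i in range(X.shape[0])
        ]
    if isinstance(eeg, EEGRecording):
        y = eeg.data
        channel_labels = eeg.channel_labels
        params.setdefault("fs", eeg.fs)
    else:
        y = np.atleast_2d(np.asarray(eeg, dtype=float))
        channel_labels = ()

    est = BoostingTRF(**params)
    lags = lag_samples(est.fs, est.tmin, est.tmax)
    folds = make_folds(X.shape[1], k)
    if stats is None:
        stats = DesignStats(X, lags, folds)
    elif stats.T != X.shape[1] or stats.P != X.shape[0]:
        raise ValueError("precomputed stats do not match the design")

    bs = stats.crosscov(y) if crosscov is None else crosscov
    yys = stats.sq_norms(y) if sq_norms is None else sq_norms
    P, L = stats.P, stats.L
    C = y.shape[0]
    kernel_sum = np.zeros((P, L, C))
    fold_acc = np.zeros((folds.k, C))
    for fold_i, (train, val, test) in enumerate(folds.rotations()):
        G_train = sum(stats.grams[s] for s in train)
        b_train = sum(bs[s] for s in train)
        sd_x = _segment_sd(stats.X, folds, train)
        sd_y = _segment_sd(y, folds, train)
        fstats = {
            "G_train": G_train,
            "b_train": b_train,
            "G_val": stats.grams[val],
            "b_val": bs[val],
            "yy_val": yys[val],
        }
        kernels, _ = est._fit_from_stats(fstats, sd_x, sd_y, L)
        kernel_sum += kernels
        seg = folds.segments[test]
        pred = (stats.lagged(test) @ kernels.reshape(P * L, C)).T
        # an all-zero kernel predicts a constant: no tracking, r = 0
        fold_acc[fold_i] = _safe_accuracy(pred, y[:, seg])
    return TRFModel(
        kernels=kernel_sum / folds.k,
        lags=lags,
        fs=est.fs,
        predictor_names=labels,
        fold_accuracies=fold_acc,
        channel_labels=tuple(channel_labels),
    )


def _safe_accuracy(pred, actual) -> np.ndarray:
    """Per-channel r with zero-variance predictions scored as 0."""
    pred = np.atleast_2d(pred)
    actual = np.atleast_2d(actual)
    p = pred - pred.mean(axis=1, keepdims=True)
    a = actual - actual.mean(axis=1, keepdims=True)
    sp = np.sqrt((p * p).sum(axis=1))
    sa = np.sqrt((a * a).sum(axis=1))
    if np.any(sa == 0):
        raise ValueError("zero-variance EEG channel in test segment")
    out = np.zeros(pred.shape[0])
    ok = sp > 0
    out[ok] = (p[ok] * a[ok]).sum(axis=1) / (sp[ok] * sa[ok])
    return out


def _segment_sd(data, folds: FoldSplit, segment_ids) -> np.ndarray:
    cols = np.concatenate([np.arange(s.start, s.stop) for s in
                           (folds.segments[i] for i in segment_ids)])
    return data[:, cols].std(axis=1)
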