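"""EEG preprocessing chain and denoising source separation (DSS).

The chain mirrors a standard continuous-speech EEG pipeline: resample to
256 Hz, optional artifact hook (identity by default), common-average
reference, 0.5-25 Hz least-squares FIR bandpass (high-pass order 5000,
low-pass order 250, stopband edges 10 % outside the passband, pass/stop
weights 100/1), resample to 128 Hz, z-scoring across conditions per channel,
and truncation to the first 455 s.  DSS estimates spatial filters whose
components are ranked by the power of the bias-filtered (2-25 Hz)
cross-recording average relative to baseline power; the top-k components are
projected back to sensor space.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EEGRecording

__all__ = [
    "design_ls_bandpass",
    "apply_bandpass",
    "common_average_reference",
    "resample_recording",
    "preprocess",
    "zscore_across_conditions",
    "truncate",
    "DSS",
    "train_dss",
    "apply_dss",
]


def _firls_odd(order: int, fs: float, bands, desired, weights) -> np.ndarray:
    """Least-squares linear-phase FIR; firls needs an even order (odd length)."""
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1
    return scipy.signal.firls(numtaps, bands, desired, weight=weights, fs=fs)


def design_ls_bandpass(
    fs: float,
    pass_lo: float = 0.5,
    pass_hi: float = 25.0,
    hp_order: int = 5000,
    lp_order: int = 250,
    stop_frac: float = 0.10,
    w_pass: float = 100.0,
    w_stop: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """High-pass + low-pass least-squares FIR pair for the 0.5-25 Hz band.

    Stopband edges sit ``stop_frac`` outside the passband edges
    (0.45 and 27.5 Hz by default).  Returns ``(hp_taps, lp_taps)``; apply
    both zero-phase (forward-backward).
    """
    if fs <= 2 * pass_hi:
        raise ValueError(f"fs={fs} too low for a {pass_hi} Hz passband edge")
    if not 0 < pass_lo < pass_hi:
        raise ValueError("need 0 < pass_lo < pass_hi")
    hp_stop = pass_lo * (1 - stop_frac)
    lp_stop = pass_hi * (1 + stop_frac)
    if lp_stop >= fs / 2:
        raise ValueError("low-pass stopband edge beyond Nyquist")
    if hp_order < 2 or lp_order < 2:
        raise ValueError("filter orders must be >= 2")
    hp = _firls_odd(
        hp_order, fs,
        bands=[0.0, hp_stop, pass_lo, fs / 2],
        desired=[0.0, 0.0, 1.0, 1.0],
        weights=[w_stop, w_pass],
    )
    lp = _firls_odd(
        lp_order, fs,
        bands=[0.0, pass_hi, lp_stop, fs / 2],
        desired=[1.0, 1.0, 0.0, 0.0],
        weights=[w_pass, w_stop],
    )
    return hp, lp


def apply_bandpass(data: np.ndarray, filt) -> np.ndarray:
    """Zero-phase application of the FIR pair along time.

    ``data`` is (channels, samples).  The least-squares filters are
    linear-phase (symmetric taps), so center-aligned FFT convolution
    (``mode='same'``) compensates the group delay exactly and leaves
    latencies untouched, with the designed magnitude response.
    """
    hp, lp = filt
    out = np.atleast_2d(np.asarray(data, dtype=float))
    for taps in (hp, lp):
        out = scipy.signal.fftconvolve(out, taps[None, :], mode="same", axes=-1)
    return out if np.asarray(data).ndim > 1 else out[0]


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel."""
    return data - data.mean(axis=0, keepdims=True)


def _resample_matrix(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_out == fs_in:
        return np.asarray(data, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return scipy.signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def resample_recording(rec: EEGRecording, fs_out: float) -> EEGRecording:
    data = _resample_matrix(rec.data, rec.fs, fs_out)
    return rec.with_data(data, fs=fs_out, step=f"resample:{rec.fs}->{fs_out}")


def preprocess(
    raw: EEGRecording,
    filt=None,
    fs_intermediate: float = 256.0,
    fs_out: float = 128.0,
    artifact_hook=None,
) -> EEGRecording:
    """Full chain: resample -> artifact hook -> CAR -> bandpass -> resample.

    ``artifact_hook`` is any channels x time -> channels x time transform
    (identity when None); it stands where a trained eye-blink filter would
    act on recorded data.
    """
    if raw.fs < fs_intermediate:
        raise ValueError(f"raw sampling rate {raw.fs} < intermediate {fs_intermediate}")
    if not raw.channel_labels or any(not c for c in raw.channel_labels):
        raise ValueError("missing channel labels")
    rec = resample_recording(raw, fs_intermediate)
    if artifact_hook is not None:
        rec = rec.with_data(artifact_hook(rec.data), step="artifact_hook")
    else:
        rec = rec.with_data(rec.data, step="artifact_hook:identity")
    rec = rec.with_data(common_average_reference(rec.data), step="car")
    if filt is None:
        filt = design_ls_bandpass(fs_intermediate)
    rec = rec.with_data(apply_bandpass(rec.data, filt), step="bandpass:0.5-25")
    rec = resample_recording(rec, fs_out)
    return rec


def zscore_across_conditions(recs: list[EEGRecording]) -> list[EEGRecording]:
    """Per channel, remove the mean and scale by the SD of the concatenation
    of all conditions; the same affine map is applied to every condition."""
    if not recs:
        raise ValueError("no recordings")
    labels = recs[0].channel_labels
    for r in recs:
        if r.channel_labels != labels:
            raise ValueError("channel labels differ across recordings")
    concat = np.concatenate([r.data for r in recs], axis=1)
    mean = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance channel(s): {[labels[i] for i in zero]}")
    return [
        r.with_data((r.data - mean) / sd, step="zscore_across_conditions")
        for r in recs
    ]


def truncate(rec: EEGRecording, seconds: float = 455.0) -> EEGRecording:
    """Keep exactly the first ``seconds * fs`` samples."""
    n = int(round(seconds * rec.fs))
    if rec.n_samples < n:
        raise ValueError(
            f"recording is {rec.duration:.1f} s, shorter than {seconds} s"
        )
    return rec.with_data(rec.data[:, :n], step=f"truncate:{seconds}s")


# ---------------------------------------------------------------------------
# Denoising source separation
# ---------------------------------------------------------------------------

class DSS(BaseEstimator, TransformerMixin):
    """Denoising source separation with an evoked (cross-recording) bias.

    Fit on multiple recordings of the same stimulus: whiten on the average
    within-recording covariance, then rotate to the directions maximizing
    the power of the bias-filtered average across recordings.  Components
    are sorted by descending power ratio (biased power / baseline power).
    ``transform`` reconstructs sensor-space data from the top
    ``n_components`` components (a rank-k projection).

    Parameters
    ----------
    n_components : number of components kept on transform (default 6).
    bias_band : (lo, hi) Hz band of the bias filter (default 2-25 Hz).
    bias_order : least-squares FIR order for the bias band filters.
    ridge : relative ridge added to the baseline covariance diagonal when
        whitening (guards rank deficiency; a warning is emitted when it
        visibly matters).
    """

    def __init__(self, n_components: int = 6, bias_band=(2.0, 25.0),
                 bias_order: int = 400, ridge: float = 1e-9):
        self.n_components = n_components
        self.bias_band = bias_band
        self.bias_order = bias_order
        self.ridge = ridge

    def fit(self, X, y=None, fs: float | None = None):
        """``X``: list of (channels, samples) arrays or EEGRecordings of equal
        shape; ``fs`` required when passing bare arrays."""
        datas, fs = _unpack_recordings(X, fs)
        if len(datas) < 2:
            raise ValueError("DSS needs at least two recordings")
        shape = datas[0].shape
        for d in datas:
            if d.shape != shape:
                raise ValueError("all recordings must share channels and length")

        datas = [d - d.mean(axis=1, keepdims=True) for d in datas]
        c_base = np.mean([d @ d.T / d.shape[1] for d in datas], axis=0)

        lam = self.ridge * np.trace(c_base) / c_base.shape[0]
        eigval, eigvec = np.linalg.eigh(c_base + lam * np.eye(c_base.shape[0]))
        tiny = eigval < 1e-12 * eigval.max()
        if tiny.any():
            warnings.warn("rank-deficient baseline covariance; ridge applied")
            eigval = np.clip(eigval, 1e-12 * eigval.max(), None)
        whiten = eigvec / np.sqrt(eigval)  # (C, C): x -> whiten.T @ x

        hp, lp = design_ls_bandpass(
            fs, pass_lo=self.bias_band[0], pass_hi=self.bias_band[1],
            hp_order=self.bias_order, lp_order=self.bias_order,
        )
        filtered = [apply_bandpass(d, (hp, lp)) for d in datas]
        grand = np.mean(filtered, axis=0)
        zb = whiten.T @ grand
        c_bias_w = zb @ zb.T / zb.shape[1]
        # per-recording (non-averaged) power in the bias band, whitened
        c_ind_w = np.mean(
            [(whiten.T @ f) @ (whiten.T @ f).T / f.shape[1] for f in filtered], axis=0
        )
        eigval, rot = np.linalg.eigh(c_bias_w)
        # repeatability ratio: N * (power of the average) / (individual power);
        # ~1 for independent noise, ~N for perfectly reproducible activity
        denom = np.einsum("ij,ij->j", rot, c_ind_w @ rot)
        ratios = len(datas) * eigval / np.maximum(denom, 1e-300)
        order = np.argsort(ratios)[::-1]
        ratios, rot = ratios[order], rot[:, order]

        self.fs_ = fs
        self.to_components_ = rot.T @ whiten.T        # (C, C): comp = W @ x
        self.from_components_ = np.linalg.pinv(self.to_components_)
        self.power_ratios_ = ratios
        self.n_channels_ = shape[0]
        return self

    def transform(self, X, k: int | None = None):
        """Project to the top-k components and back to sensor space."""
        k = self.n_components if k is None else k
        if k > self.to_components_.shape[0]:
            raise ValueError(f"k={k} exceeds component count")
        single = not isinstance(X, (list, tuple))
        items = [X] if single else list(X)
        out = []
        for item in items:
            data = item.data if isinstance(item, EEGRecording) else np.asarray(item, dtype=float)
            if data.shape[0] != self.n_channels_:
                raise ValueError("channel count differs from training data")
            proj = self.from_components_[:, :k] @ (self.to_components_[:k] @ data)
            if isinstance(item, EEGRecording):
                out.append(item.with_data(proj, step=f"dss:k={k}"))
            else:
                out.append(proj)
        return out[0] if single else out


def _unpack_recordings(X, fs):
    datas = []
    for item in X:
        if isinstance(item, EEGRecording):
            datas.append(item.data)
            if fs is None:
                fs = item.fs
            elif fs != item.fs:
                raise ValueError("sampling rates differ across recordings")
        else:
            datas.append(np.asarray(item, dtype=float))
    if fs is None:
        raise ValueError("fs required when passing bare arrays")
    return datas, fs


def train_dss(recs, bias_band=(2.0, 25.0), bias_order: int = 400, fs=None) -> DSS:
    """Functional wrapper: fit a :class:`DSS` on recordings of one stimulus."""
    return DSS(bias_band=bias_band, bias_order=bias_order).fit(recs, fs=fs)


def apply_dss(rec, dss: DSS, k: int = 6):
    """Project a recording through the top-k DSS components (sensor space)."""
    return dss.transform(rec, k=k)
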