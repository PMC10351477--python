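"""Tracking measures and TRF peak characteristics.

*Acoustic tracking* is the held-out prediction accuracy of the acoustic
model; *language tracking* is the per-channel increase in accuracy of the
complete model over the acoustic + (pre)lexical baseline.  Peaks are the
signed extrema of selection-averaged TRFs inside a-priori lag windows; an
extremum sitting on a window edge is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import CENTRAL_SELECTION, FRONTAL_SELECTION, selection_indices
from .trf import TRFModel

__all__ = [
    "ChannelSelection",
    "FRONTAL",
    "CENTRAL",
    "PeakWindow",
    "PEAK_WINDOWS",
    "PeakResult",
    "selection_average",
    "tracking_increase",
    "average_multiband_trf",
    "detect_peak",
]


@dataclass(frozen=True)
class ChannelSelection:
    name: str
    labels: tuple[str, ...]


FRONTAL = ChannelSelection("frontal", FRONTAL_SELECTION)
CENTRAL = ChannelSelection("central", CENTRAL_SELECTION)


@dataclass(frozen=True)
class PeakWindow:
    """A-priori lag window for one named TRF peak."""

    feature: str
    t_lo: float  # ms
    t_hi: float  # ms
    polarity: str  # 'positive' | 'negative'
    peak_name: str


#: Default peak windows per feature (ms) with expected polarity.
PEAK_WINDOWS: tuple[PeakWindow, ...] = (
    PeakWindow("spectrogram", 0, 65, "positive", "P1"),
    PeakWindow("spectrogram", 70, 110, "negative", "N1"),
    PeakWindow("spectrogram", 115, 200, "positive", "P2"),
    PeakWindow("edges", 0, 90, "positive", "P1"),
    PeakWindow("edges", 95, 140, "negative", "N1"),
    PeakWindow("phoneme_surprisal", 150, 350, "negative", "N250"),
    PeakWindow("cohort_entropy", 150, 350, "negative", "N250"),
    PeakWindow("word_surprisal", 300, 500, "negative", "N400"),
    PeakWindow("word_frequency", 300, 500, "negative", "N400"),
)


@dataclass
class PeakResult:
    """Outcome of peak detection within one window."""

    found: bool
    amplitude: float | None = None
    latency_ms: float | None = None
    wrong_sign: bool = False
    subject_id: str = ""
    feature: str = ""
    condition: str = ""
    peak_name: str = ""


def selection_average(values: np.ndarray, channel_labels, selection: ChannelSelection):
    """Unweighted mean over the selection's channels.

    ``values`` has channels on the last axis (channel vector or lag series
    stacked as (..., C)); the result drops that axis.
    """
    idx = selection_indices(channel_labels, selection.labels)
    values = np.asarray(values, dtype=float)
    return values[..., idx].mean(axis=-1)


def tracking_increase(complete: TRFModel, baseline: TRFModel):
    """Per-channel accuracy increase of the complete over the baseline model.

    Returns ``(delta_mean, delta_folds)``: the per-channel mean difference
    and the per-fold differences for paired statistics.
    """
    if complete.fold_accuracies.shape != baseline.fold_accuracies.shape:
        raise ValueError("models have different fold/channel structure")
    if complete.channel_labels != baseline.channel_labels:
        raise ValueError("models have different channel labels")
    delta_folds = complete.fold_accuracies - baseline.fold_accuracies
    return delta_folds.mean(axis=0), delta_folds


def average_multiband_trf(kernels: np.ndarray) -> np.ndarray:
    """Mean kernel over frequency bands: (n_bands, L, C) -> (L, C)."""
    kernels = np.asarray(kernels, dtype=float)
    if kernels.ndim != 3 or kernels.shape[0] < 1:
        raise ValueError("expected (n_bands, n_lags, n_channels) kernels")
    return kernels.mean(axis=0)


def detect_peak(trf: np.ndarray, lags_ms: np.ndarray, window: PeakWindow, **ids) -> PeakResult:
    """Signed extremum of a selection-averaged TRF within a lag window.

    The extremum matching the window polarity is located over the samples
    with ``t_lo <= lag <= t_hi``; if it falls on the first or last window
    sample the peak is discarded (``found=False``).  Ties resolve to the
    earliest lag.  A negative-polarity peak with positive amplitude (or
    vice versa) is still reported but flagged ``wrong_sign``.
    """
    trf = np.asarray(trf, dtype=float).ravel()
    lags_ms = np.asarray(lags_ms, dtype=float)
    if trf.shape != lags_ms.shape:
        raise ValueError("TRF and lag axis lengths differ")
    if window.t_lo < lags_ms[0] or window.t_hi > lags_ms[-1]:
        raise ValueError(
            f"window {window.t_lo}-{window.t_hi} ms outside lag axis "
            f"{lags_ms[0]:.0f}-{lags_ms[-1]:.0f} ms"
        )
    mask = (lags_ms >= window.t_lo) & (lags_ms <= window.t_hi)
    idx = np.nonzero(mask)[0]
    values = trf[idx]
    if window.polarity == "positive":
        rel = int(np.argmax(values))
    elif window.polarity == "negative":
        rel = int(np.argmin(values))
    else:
        raise ValueError(f"unknown polarity {window.polarity!r}")
    meta = dict(feature=window.feature, peak_name=window.peak_name, **ids)
    if rel in (0, len(idx) - 1):
        return PeakResult(found=False, **meta)
    amplitude = float(values[rel])
    wrong_sign = (amplitude > 0) if window.polarity == "negative" else (amplitude < 0)
    return PeakResult(
        found=True,
        amplitude=amplitude,
        latency_ms=float(lags_ms[idx[rel]]),
        wrong_sign=wrong_sign,
        **meta,
    )
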