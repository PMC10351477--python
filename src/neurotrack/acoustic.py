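"""Acoustic speech regressors: gammatone spectrogram and acoustic edges.

The spectrogram is a 256-channel gammatone filterbank (4th-order filters,
ERB-spaced center frequencies between 70 and 4000 Hz) whose output energy is
integrated over 10 ms windows, averaged into 8 broad bands (32 consecutive
channels each), and resampled onto the 128 Hz EEG analysis grid.  Acoustic
edges are the half-wave rectified first difference of the spectrogram.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .containers import Spectrogram

__all__ = [
    "erb_space",
    "compute_gammatone_spectrogram",
    "band_average",
    "compute_acoustic_edges",
    "resample_to_grid",
    "acoustic_feature_set",
]


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """``n`` center frequencies equally spaced on the ERB-rate scale.

    Uses the Glasberg & Moore ERB-rate mapping
    ``ERBrate(f) = 21.4 * log10(1 + 0.00437 f)``.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")

    def to_erb(f):
        return 21.4 * np.log10(1.0 + 0.00437 * f)

    def from_erb(e):
        return (10.0 ** (e / 21.4) - 1.0) / 0.00437

    return from_erb(np.linspace(to_erb(f_lo), to_erb(f_hi), n))


def compute_gammatone_spectrogram(
    samples: np.ndarray,
    fs: float,
    n_channels: int = 256,
    f_lo: float = 70.0,
    f_hi: float = 4000.0,
    integration: float = 0.01,
    order: int = 4,
) -> Spectrogram:
    """Gammatone filterbank energy, integrated over ``integration`` seconds.

    Each channel is a 4th-order gammatone IIR filter; the per-channel output
    power is averaged over consecutive non-overlapping 10 ms windows, giving
    a frame rate of ``1/integration`` (100 frames/s by default).

    Parameters
    ----------
    samples : 1-D waveform.
    fs : waveform sampling rate (Hz); must satisfy the Nyquist bound for
        ``f_hi``.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty audio")
    if fs < 2 * f_hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low; need at least {2 * f_hi} Hz "
            f"for a {f_hi} Hz upper band edge"
        )
    duration = samples.size / fs
    if duration <= integration:
        raise ValueError("audio shorter than one integration window")

    centers = erb_space(f_lo, f_hi, n_channels)
    hop = int(round(integration * fs))
    n_frames = samples.size // hop
    out = np.empty((n_frames, n_channels))
    trimmed = samples[: n_frames * hop]
    nyq = fs / 2.0
    for ch, fc in enumerate(centers):
        # scipy's gammatone design is 4th order for ftype="iir"; a center at
        # exactly Nyquist is nudged just below it
        b, a = scipy.signal.gammatone(min(fc, nyq * (1 - 1e-9)), "iir", fs=fs)
        if order != 4:
            raise ValueError("only the standard 4th-order gammatone is supported")
        y = scipy.signal.lfilter(b, a, trimmed)
        power = y * y
        out[:, ch] = power.reshape(n_frames, hop).mean(axis=1)
    return Spectrogram(values=np.sqrt(out), fs=1.0 / integration, band_centers=centers)


def band_average(spec: Spectrogram, group: int = 32) -> Spectrogram:
    """Average consecutive filter channels into broad bands (256 -> 8)."""
    n_bands = spec.n_bands
    if n_bands % group:
        raise ValueError(f"band count {n_bands} not divisible by {group}")
    n_out = n_bands // group
    values = spec.values.reshape(spec.n_frames, n_out, group).mean(axis=2)
    centers = spec.band_centers.reshape(n_out, group).mean(axis=1)
    return Spectrogram(values=values, fs=spec.fs, band_centers=centers)


def compute_acoustic_edges(spec: Spectrogram) -> Spectrogram:
    """Half-wave rectified frame-to-frame derivative of the spectrogram.

    The first frame is defined as 0 so the output keeps the input shape;
    negative derivative values are clipped to 0.
    """
    if spec.n_frames < 2:
        raise ValueError("need at least two frames to differentiate")
    edges = np.zeros_like(spec.values)
    edges[1:] = np.clip(np.diff(spec.values, axis=0), 0.0, None)
    return Spectrogram(values=edges, fs=spec.fs, band_centers=spec.band_centers)


def resample_to_grid(spec: Spectrogram, fs_out: float = 128.0) -> Spectrogram:
    """Polyphase-resample the spectrogram frames onto the EEG grid.

    Anti-aliasing is inherent to polyphase resampling; tiny negative values
    introduced by filter ringing are clipped to 0 because the features
    represent energy.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out > spec.fs:
        raise ValueError("upsampling the feature grid is not supported")
    if fs_out == spec.fs:
        return Spectrogram(spec.values.copy(), spec.fs, spec.band_centers)
    from fractions import Fraction

    frac = Fraction(fs_out / spec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    values = scipy.signal.resample_poly(spec.values, up, down, axis=0)
    n_out = int(round(spec.n_frames * fs_out / spec.fs))
    values = values[:n_out]
    return Spectrogram(values=np.clip(values, 0.0, None), fs=fs_out, band_centers=spec.band_centers)


def acoustic_feature_set(
    samples: np.ndarray,
    fs: float,
    fs_out: float = 128.0,
    edges_on_bands: bool = True,
) -> dict[str, Spectrogram]:
    """Full acoustic front-end: spectrogram (8 bands) and edges at ``fs_out``.

    ``edges_on_bands`` selects whether the derivative is taken after band
    averaging (default) or on the 256-channel filterbank output before
    averaging.
    """
    spec256 = compute_gammatone_spectrogram(samples, fs)
    spec8 = band_average(spec256)
    if edges_on_bands:
        edges = compute_acoustic_edges(spec8)
    else:
        edges = band_average(compute_acoustic_edges(spec256))
    return {
        "spectrogram": resample_to_grid(spec8, fs_out),
        "edges": resample_to_grid(edges, fs_out),
    }
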