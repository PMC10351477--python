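"""In-memory containers shared across the pipeline.

Everything downstream of feature extraction operates on a common 128 Hz time
grid; these containers carry the arrays together with the metadata needed to
keep stages honest (sampling rates, channel labels, applied-step provenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Spectrogram:
    """Time x band energy matrix with its frame rate and band centers (Hz)."""

    values: np.ndarray  # (n_frames, n_bands), non-negative
    fs: float
    band_centers: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (frames x bands)")
        if self.values.shape[1] != len(self.band_centers):
            raise ValueError("band_centers length must match number of bands")
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureSet:
    """Named bank of regressors on a common sampling grid.

    Each feature is stored as an ``(n_arrays, T)`` matrix: dense band
    features (spectrogram, edges) have one row per band, impulse features a
    single row.
    """

    fs: float
    n_samples: int
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, data: np.ndarray) -> None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] != self.n_samples:
            raise ValueError(
                f"feature {name!r} has {data.shape[1]} samples, expected {self.n_samples}"
            )
        self.features[name] = data

    def __getitem__(self, name: str) -> np.ndarray:
        return self.features[name]

    def __contains__(self, name: str) -> bool:
        return name in self.features

    @property
    def names(self) -> list[str]:
        return list(self.features)

    def design_matrix(self, names=None) -> tuple[np.ndarray, list[str]]:
        """Stack selected features into an ``(n_arrays, T)`` design, with
        one descriptive label per row (``name[band]`` for multi-band)."""
        if names is None:
            names = self.names
        rows, labels = [], []
        for name in names:
            if name not in self.features:
                raise KeyError(f"feature {name!r} not in set")
            block = self.features[name]
            rows.append(block)
            if block.shape[0] == 1:
                labels.append(name)
            else:
                labels.extend(f"{name}[{b}]" for b in range(block.shape[0]))
        return np.vstack(rows), labels


@dataclass
class EEGRecording:
    """Channels x samples EEG with labels, sampling rate and provenance."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: tuple[str, ...]
    condition_id: str = ""
    meta: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match channel count")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None, step: str | None = None):
        """Return a copy with new data and an appended provenance step."""
        new = replace(
            self,
            data=np.asarray(data, dtype=float),
            fs=self.fs if fs is None else fs,
            meta=list(self.meta),
        )
        if step:
            new.meta.append(step)
        return new
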