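"""Self-describing HDF5 containers and raw EEG readers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EEGRecording, FeatureSet
from .trf import TRFModel

__all__ = [
    "save_features", "load_features",
    "save_eeg", "load_eeg",
    "save_trf", "load_trf",
    "read_raw_binary", "read_edf",
]


def save_features(fset: FeatureSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["fs"] = fset.fs
        fh.attrs["n_samples"] = fset.n_samples
        grp = fh.create_group("features")
        for name, data in fset.features.items():
            grp.create_dataset(name, data=data)


def load_features(path) -> FeatureSet:
    with h5py.File(path, "r") as fh:
        fset = FeatureSet(fs=float(fh.attrs["fs"]), n_samples=int(fh.attrs["n_samples"]))
        for name, ds in fh["features"].items():
            fset.add(name, ds[()])
    return fset


def save_eeg(rec: EEGRecording, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data)
        fh.attrs["fs"] = rec.fs
        fh.attrs["channel_labels"] = list(rec.channel_labels)
        fh.attrs["condition_id"] = rec.condition_id
        fh.attrs["meta"] = json.dumps(rec.meta)


def load_eeg(path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        return EEGRecording(
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            channel_labels=tuple(str(c) for c in fh.attrs["channel_labels"]),
            condition_id=str(fh.attrs["condition_id"]),
            meta=json.loads(fh.attrs["meta"]),
        )


def save_trf(trf: TRFModel, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kernels", data=trf.kernels)
        fh.create_dataset("lags_ms", data=trf.lags_ms)
        fh.create_dataset("fold_accuracies", data=trf.fold_accuracies)
        fh.attrs["fs"] = trf.fs
        fh.attrs["predictor_names"] = list(trf.predictor_names)
        fh.attrs["channel_labels"] = list(trf.channel_labels)


def load_trf(path) -> TRFModel:
    with h5py.File(path, "r") as fh:
        fs = float(fh.attrs["fs"])
        lags = np.round(fh["lags_ms"][()] / 1000.0 * fs).astype(int)
        return TRFModel(
            kernels=fh["kernels"][()],
            lags=lags,
            fs=fs,
            predictor_names=[str(n) for n in fh.attrs["predictor_names"]],
            fold_accuracies=fh["fold_accuracies"][()],
            channel_labels=tuple(str(c) for c in fh.attrs["channel_labels"]),
        )


def read_raw_binary(data_path, header_path=None) -> EEGRecording:
    """Read float32 channel-major raw EEG with a JSON sidecar header
    ``{"fs": ..., "channel_labels": [...], "condition_id": ...}``."""
    data_path = Path(data_path)
    if header_path is None:
        header_path = data_path.with_suffix(".json")
    header = json.loads(Path(header_path).read_text())
    labels = header["channel_labels"]
    raw = np.fromfile(data_path, dtype=np.float32)
    n_ch = len(labels)
    if raw.size % n_ch:
        raise ValueError("raw size not divisible by channel count")
    return EEGRecording(
        data=raw.reshape(n_ch, -1).astype(float),
        fs=float(header["fs"]),
        channel_labels=tuple(labels),
        condition_id=str(header.get("condition_id", "")),
    )


def read_edf(path, condition_id: str = "") -> EEGRecording:
    """Read EDF/BDF via mne into an EEGRecording."""
    import mne

    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        condition_id=condition_id,
    )
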