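"""Standard 64-channel 10-20 geometry: labels, flat positions, selections, adjacency.

The head geometry comes from the standard BioSemi 64-electrode montage.  Two
a-priori channel selections are exposed: a fronto-central selection used for
acoustic responses and a centro-parietal selection used for language
responses.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial import Delaunay

#: Fronto-central selection used for acoustic / (pre)lexical peak analysis.
FRONTAL_SELECTION = (
    "F5", "F3", "F1", "Fz", "F2", "F4", "F6",
    "FC5", "FC1", "FC3", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
)

#: Centro-parietal selection used for language-feature peak analysis.
CENTRAL_SELECTION = ("P1", "Pz", "P2", "CP1", "CPz", "CP2")


@lru_cache(maxsize=None)
def standard_64_labels() -> tuple[str, ...]:
    """Channel labels of the standard BioSemi 64 montage (10-20 names)."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    return tuple(montage.ch_names)


@lru_cache(maxsize=None)
def _positions_3d() -> np.ndarray:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[name] for name in montage.ch_names], dtype=float)


def positions_2d(labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Azimuthal-equidistant projection of electrode positions to the plane.

    Electrodes on a sphere are flattened by preserving the polar angle from
    the vertex as radius, which keeps neighbourhood structure intact for
    triangulation-based adjacency.
    """
    xyz = _positions_3d()
    all_labels = standard_64_labels()
    xyz = xyz - xyz.mean(axis=0)
    r = np.linalg.norm(xyz, axis=1)
    unit = xyz / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    rho = np.hypot(unit[:, 0], unit[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 0, theta / rho, 0.0)
    flat = unit[:, :2] * scale[:, None]
    if labels is None:
        return flat
    index = {name: i for i, name in enumerate(all_labels)}
    missing = [name for name in labels if name not in index]
    if missing:
        raise KeyError(f"unknown channel labels: {missing}")
    return flat[[index[name] for name in labels]]


def channel_adjacency(labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Boolean channel x channel adjacency from Delaunay triangulation.

    Channels sharing an edge of the Delaunay triangulation of the flattened
    montage are neighbours.  The matrix is symmetric with a False diagonal.
    """
    if labels is None:
        labels = standard_64_labels()
    pts = positions_2d(tuple(labels))
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    if n < 3:
        adj[:] = ~np.eye(n, dtype=bool)
        return adj
    tri = Delaunay(pts)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True
    return adj


def selection_indices(labels, selection) -> np.ndarray:
    """Indices of ``selection`` labels within ``labels`` (error on missing)."""
    index = {name: i for i, name in enumerate(labels)}
    out = []
    for name in selection:
        if name not in index:
            raise KeyError(f"channel {name!r} not present in recording")
        out.append(index[name])
    return np.asarray(out, dtype=int)
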