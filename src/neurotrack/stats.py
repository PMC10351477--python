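"""Group-level inference: nonparametric pairwise tests, multiple-comparison
corrections, and spatio-temporal cluster-based permutation tests.

The cluster test is a one-sample test against zero on per-subject maps
(channel vectors, selection-averaged lag series, or channel x lag matrices):
cells whose one-sample t-test p-value falls below ``cluster_p_min`` are
grouped by adjacency into signed clusters, each scored by its mass (sum of
t); the family-wise null distribution is the maximum absolute cluster mass
over random per-subject sign flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_paired",
    "mannwhitney_u",
    "bh_adjust",
    "holm_adjust",
    "correct_three",
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
]


def wilcoxon_paired(x, y, exact_max_n: int = 25):
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null is used up to ``exact_max_n`` remaining pairs, the normal
    approximation beyond.  Returns ``(W, p)``.  All-zero differences give
    ``p = 1`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = x - y
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return 0.0, 1.0
    method = "exact" if n_nonzero <= exact_max_n else "approx"
    try:
        res = scipy.stats.wilcoxon(
            x, y, zero_method="wilcox", alternative="two-sided", method=method
        )
    except ValueError:
        res = scipy.stats.wilcoxon(
            x, y, zero_method="wilcox", alternative="two-sided", method="approx"
        )
    return float(res.statistic), float(res.pvalue)


def mannwhitney_u(x, y):
    """Two-sided Mann-Whitney U test (tie-corrected normal approximation).

    Returns ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need at least 3 observations")
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def correct_three(pvalues, method: str = "bh") -> np.ndarray:
    """Adjust exactly three p-values (the three condition comparisons)."""
    p = np.asarray(pvalues, dtype=float)
    if p.shape != (3,):
        raise ValueError("correct_three expects exactly 3 p-values")
    if method == "bh":
        return bh_adjust(p)
    if method == "holm":
        return holm_adjust(p)
    raise ValueError("method must be 'bh' or 'holm'")


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cells: np.ndarray        # flat cell indices into the map
    mass: float              # sum of t within the cluster
    p_value: float
    sign: int                # +1 / -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold: float
    alpha: float = 0.05
    shape: tuple = ()
    seed: int | None = None

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha]


def _cell_adjacency(shape, channel_adjacency):
    """Sparse adjacency over flattened map cells.

    1-D maps chain along the axis; (C,) maps use ``channel_adjacency``;
    (C, L) maps connect channel neighbours at equal lag and equal channels
    at neighbouring lags.
    """
    if len(shape) == 1:
        n = shape[0]
        if channel_adjacency is not None:
            adj = np.asarray(channel_adjacency, dtype=bool)
            if adj.shape != (n, n):
                raise ValueError("adjacency shape does not match map")
            _check_connected(adj)
            return scipy.sparse.csr_matrix(adj)
        i = np.arange(n - 1)
        return scipy.sparse.coo_matrix(
            (np.ones(2 * (n - 1), dtype=bool),
             (np.r_[i, i + 1], np.r_[i + 1, i])), shape=(n, n)
        ).tocsr()
    if len(shape) == 2:
        C, L = shape
        if channel_adjacency is None:
            raise ValueError("channel adjacency required for channel x lag maps")
        adj = np.asarray(channel_adjacency, dtype=bool)
        if adj.shape != (C, C):
            raise ValueError("adjacency shape does not match channel count")
        _check_connected(adj)
        rows, cols = [], []
        ai, aj = np.nonzero(adj)
        for lag in range(L):
            rows.append(ai * L + lag)
            cols.append(aj * L + lag)
        base = np.arange(C)[:, None] * L + np.arange(L - 1)[None, :]
        rows.append(base.ravel())
        cols.append((base + 1).ravel())
        rows.append((base + 1).ravel())
        cols.append(base.ravel())
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        n = C * L
        return scipy.sparse.coo_matrix(
            (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
        ).tocsr()
    raise ValueError("maps must be (C,), (L,) or (C, L) per subject")


def _check_connected(adj):
    isolated = np.nonzero(~adj.any(axis=1))[0]
    if isolated.size:
        raise ValueError(f"adjacency has disconnected channel(s) at index {isolated.tolist()}")


def _t_stats(data):
    """One-sample t against 0 along axis 0; zero-variance cells give t=0."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _clusters_from_t(t_flat, threshold, cell_adj):
    """Signed suprathreshold clusters and their masses."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_flat) > threshold
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        if idx.size == 1:
            out.append((idx, float(t_flat[idx[0]]), sign))
            continue
        sub = cell_adj[idx][:, idx]
        n_comp, labels = scipy.sparse.csgraph.connected_components(sub, directed=False)
        for comp in range(n_comp):
            cells = idx[labels == comp]
            out.append((cells, float(t_flat[cells].sum()), sign))
    return out


def cluster_permutation(
    maps,
    channel_adjacency=None,
    alpha: float = 0.05,
    cluster_p_min: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """One-sample cluster-based permutation test against zero.

    Parameters
    ----------
    maps : (n_subjects, ...) array; per-subject map of shape (C,), (L,) or
        (C, L).
    channel_adjacency : boolean channel x channel matrix; required when the
        map has a channel axis, ignored for lag-only maps.
    cluster_p_min : per-cell two-sided p threshold for cluster forming.
    n_perm : number of random sign-flip permutations.

    Cluster p-values are ``(1 + #{null >= observed}) / (1 + n_perm)`` with
    the null being the maximum absolute cluster mass per permutation.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 5:
        raise ValueError("need at least 5 subjects")
    shape = maps.shape[1:]
    flat = maps.reshape(n_sub, -1)
    t_thresh = scipy.stats.t.ppf(1.0 - cluster_p_min / 2.0, df=n_sub - 1)
    cell_adj = _cell_adjacency(shape, channel_adjacency)

    t_obs = _t_stats(flat)
    observed = _clusters_from_t(t_obs, t_thresh, cell_adj)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    if observed:
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
        for i in range(n_perm):
            t_p = _t_stats(flips[i][:, None] * flat)
            perm_clusters = _clusters_from_t(t_p, t_thresh, cell_adj)
            if perm_clusters:
                null_max[i] = max(abs(m) for _, m, _ in perm_clusters)

    clusters = [
        Cluster(
            cells=cells,
            mass=mass,
            p_value=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
            sign=sign,
        )
        for cells, mass, sign in observed
    ]
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, t_map=t_obs.reshape(shape), threshold=float(t_thresh),
        alpha=alpha, shape=shape, seed=seed,
    )
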