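"""Full study replica: features -> preprocessing -> nested TRF models ->
tracking analysis -> group statistics, from one config.

Three nested encoding models are fitted per subject and condition:

* acoustic  = {spectrogram, edges}
* baseline  = acoustic + {phoneme onsets, word onsets}
* complete  = baseline + {phoneme surprisal, cohort entropy,
               word surprisal, word frequency}

The added value of the language features is the per-channel increase in
cross-validated prediction accuracy of the complete over the baseline model;
its significance across subjects is assessed with a cluster-based
permutation test, acoustic tracking differences with paired Wilcoxon tests
(BH corrected), and N400-window peak amplitudes with Mann-Whitney U tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .containers import EEGRecording, FeatureSet
from .montage import channel_adjacency
from .preprocessing import DSS, zscore_across_conditions
from .simulate import (
    ACOUSTIC_FEATURES,
    LANGUAGE_FEATURES,
    LEXICAL_FEATURES,
    SimConfig,
    simulate_study,
)
from .stats import bh_adjust, cluster_permutation, mannwhitney_u, wilcoxon_paired
from .tracking import CENTRAL, FRONTAL, PEAK_WINDOWS, detect_peak, selection_average, tracking_increase
from .trf import DesignStats, TRFModel, crossval_trf, lag_samples, make_folds

__all__ = ["StudyConfig", "StudyResult", "run_study", "MODEL_FEATURES"]

MODEL_FEATURES = {
    "acoustic": list(ACOUSTIC_FEATURES),
    "baseline": list(ACOUSTIC_FEATURES + LEXICAL_FEATURES),
    "complete": list(ACOUSTIC_FEATURES + LEXICAL_FEATURES + LANGUAGE_FEATURES),
}


@dataclass
class StudyConfig:
    """Configuration of the full replica run."""

    sim: SimConfig = field(default_factory=SimConfig)
    cv_folds: int = 10
    n_perm: int = 500
    alpha: float = 0.05
    dss_k: int | None = None          # None disables DSS
    trf_params: dict = field(default_factory=dict)

    def __post_init__(self):
        sets = [set(MODEL_FEATURES[m]) for m in ("acoustic", "baseline", "complete")]
        if not (sets[0] <= sets[1] <= sets[2]):
            raise ValueError("model predictor sets must be nested")


@dataclass
class StudyResult:
    """Everything the replica computes, plus provenance."""

    config: StudyConfig
    models: dict          # condition -> model -> list[TRFModel] per subject
    delta_language: dict  # condition -> (n_subjects, C) complete - baseline
    delta_lexical: dict   # condition -> (n_subjects, C) baseline - acoustic
    acoustic_accuracy: dict  # condition -> (n_subjects, C)
    clusters_language: dict  # condition -> ClusterResult on delta_language
    acoustic_comparisons: list  # (pair, W, p_raw, p_adj) frontal acoustic accuracy
    peaks: dict           # condition -> feature -> list[PeakResult]
    peak_comparisons: dict  # feature -> list of (pair, U, p_raw, p_adj)
    trf_clusters: dict    # condition -> feature -> ClusterResult (lag-only)
    provenance: dict

    def peak_counts(self) -> dict:
        """found / total tallies per feature and condition."""
        out = {}
        for cond, feats in self.peaks.items():
            for feat, results in feats.items():
                out.setdefault(feat, {})[cond] = sum(r.found for r in results)
        return out


def _subject_trfs(features: FeatureSet, recs: list[EEGRecording],
                  cv_folds: int, trf_params: dict):
    """Fit the three nested models for every subject of one condition,
    sharing the lagged-design statistics across subjects and models."""
    X, labels = features.design_matrix(MODEL_FEATURES["complete"])
    fs = features.fs
    params = dict(trf_params)
    params.setdefault("fs", fs)
    lags = lag_samples(params["fs"],
                       params.get("tmin", -0.1), params.get("tmax", 0.6))
    folds = make_folds(features.n_samples, cv_folds)
    stats = DesignStats(X, lags, folds)

    # map model -> predictor row ids within the complete design
    row_of = {}
    row = 0
    for name in MODEL_FEATURES["complete"]:
        n_rows = features[name].shape[0]
        row_of[name] = list(range(row, row + n_rows))
        row += n_rows
    model_stats = {}
    for model, feats in MODEL_FEATURES.items():
        ids = [r for f in feats for r in row_of[f]]
        model_stats[model] = stats.subset(ids) if len(ids) < stats.P else stats

    out = {m: [] for m in MODEL_FEATURES}
    for rec in recs:
        # feature-EEG cross-covariances are shared between nested models
        bs_full = stats.crosscov(rec.data)
        yys = stats.sq_norms(rec.data)
        for model, feats in MODEL_FEATURES.items():
            sub_labels = [
                lab for f in feats for lab in
                ([f] if features[f].shape[0] == 1 else
                 [f"{f}[{b}]" for b in range(features[f].shape[0])])
            ]
            mstats = model_stats[model]
            idx = mstats._col_idx
            bs = bs_full if idx is None else [b[idx] for b in bs_full]
            out[model].append(crossval_trf(
                mstats.X, rec.data, feature_names=sub_labels,
                k=cv_folds, stats=mstats, crosscov=bs, sq_norms=yys, **params,
            ))
    for model in out:
        for trf in out[model]:
            trf.channel_labels = recs[0].channel_labels
    return out


def _feature_trf(trf: TRFModel, feature: str) -> np.ndarray:
    """(L, C) kernel for one feature, averaging multi-band features."""
    rows = [i for i, n in enumerate(trf.predictor_names)
            if n == feature or n.startswith(f"{feature}[")]
    if not rows:
        raise KeyError(f"feature {feature!r} not in model")
    return trf.kernels[rows].mean(axis=0)


def run_study(config: StudyConfig, data: dict | None = None) -> StudyResult:
    """Run the whole replica on simulated (or pre-generated) study data."""
    if data is None:
        data = simulate_study(config.sim)
    sim = data["config"]
    conditions = list(sim.conditions)
    features = data["features"]
    eeg = data["eeg"]

    # per-subject z-scoring across the three conditions (and optional DSS)
    n_subjects = len(eeg[conditions[0]])
    for s in range(n_subjects):
        recs = zscore_across_conditions([eeg[c][s] for c in conditions])
        for c, r in zip(conditions, recs):
            eeg[c][s] = r
    if config.dss_k is not None:
        for c in conditions:
            dss = DSS(n_components=config.dss_k).fit(eeg[c])
            eeg[c] = dss.transform(eeg[c])

    models = {}
    for cond in conditions:
        models[cond] = _subject_trfs(
            features[cond], eeg[cond], config.cv_folds, config.trf_params
        )

    channel_labels = eeg[conditions[0]][0].channel_labels
    adjacency = channel_adjacency(channel_labels)
    seed = sim.seed

    delta_language, delta_lexical, acoustic_acc = {}, {}, {}
    clusters_language = {}
    for cond in conditions:
        d_lang, d_lex, acc = [], [], []
        for s in range(n_subjects):
            dl, _ = tracking_increase(models[cond]["complete"][s],
                                      models[cond]["baseline"][s])
            dx, _ = tracking_increase(models[cond]["baseline"][s],
                                      models[cond]["acoustic"][s])
            d_lang.append(dl)
            d_lex.append(dx)
            acc.append(models[cond]["acoustic"][s].mean_accuracy)
        delta_language[cond] = np.array(d_lang)
        delta_lexical[cond] = np.array(d_lex)
        acoustic_acc[cond] = np.array(acc)
        clusters_language[cond] = cluster_permutation(
            delta_language[cond], channel_adjacency=adjacency,
            alpha=config.alpha, n_perm=config.n_perm, seed=seed + 101,
        )

    # acoustic tracking: pairwise Wilcoxon on frontal-averaged accuracies
    frontal_acc = {
        c: selection_average(acoustic_acc[c], channel_labels, FRONTAL)
        for c in conditions
    }
    pairs = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]]
    raw = []
    stats_w = []
    for a, b in pairs:
        w, p = wilcoxon_paired(frontal_acc[a], frontal_acc[b])
        stats_w.append(w)
        raw.append(p)
    adj = bh_adjust(raw)
    acoustic_comparisons = [
        (pair, w, p, pa) for pair, w, p, pa in zip(pairs, stats_w, raw, adj)
    ]

    # peaks: language features on central selection, acoustic on frontal
    peaks = {c: {} for c in conditions}
    trf_clusters = {c: {} for c in conditions}
    for cond in conditions:
        for window in PEAK_WINDOWS:
            feat = window.feature
            selection = CENTRAL if feat in LANGUAGE_FEATURES else FRONTAL
            series = []
            for s in range(n_subjects):
                trf = models[cond]["complete"][s]
                lagc = _feature_trf(trf, feat)  # (L, C)
                series.append(selection_average(lagc, channel_labels, selection))
            series = np.array(series)  # (n_subjects, L)
            lags_ms = models[cond]["complete"][0].lags_ms
            results = [
                detect_peak(series[s], lags_ms, window,
                            subject_id=f"S{s:02d}", condition=cond)
                for s in range(n_subjects)
            ]
            if window.peak_name in ("N250", "N400"):
                peaks[cond][feat] = results
                trf_clusters[cond][feat] = cluster_permutation(
                    series, alpha=config.alpha, n_perm=config.n_perm,
                    seed=seed + 202,
                )
            else:
                peaks[cond][f"{feat}:{window.peak_name}"] = results

    # amplitude comparisons between conditions (unequal n -> Mann-Whitney U)
    peak_comparisons = {}
    for feat in LANGUAGE_FEATURES:
        raw_p, stats_u, kept = [], [], []
        for a, b in pairs:
            amp_a = [r.amplitude for r in peaks[a][feat] if r.found]
            amp_b = [r.amplitude for r in peaks[b][feat] if r.found]
            if len(amp_a) < 3 or len(amp_b) < 3:
                continue
            u, p = mannwhitney_u(amp_a, amp_b)
            stats_u.append(u)
            raw_p.append(p)
            kept.append((a, b))
        adj_p = bh_adjust(raw_p) if raw_p else []
        peak_comparisons[feat] = [
            (pair, u, p, pa) for pair, u, p, pa in zip(kept, stats_u, raw_p, adj_p)
        ]

    provenance = {
        "seed": sim.seed,
        "sim_config": dataclasses.asdict(sim),
        "cv_folds": config.cv_folds,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "dss_k": config.dss_k,
        "trf_params": dict(config.trf_params),
    }
    return StudyResult(
        config=config,
        models=models,
        delta_language=delta_language,
        delta_lexical=delta_lexical,
        acoustic_accuracy=acoustic_acc,
        clusters_language=clusters_language,
        acoustic_comparisons=acoustic_comparisons,
        peaks=peaks,
        peak_comparisons=peak_comparisons,
        trf_clusters=trf_clusters,
        provenance=provenance,
    )


def summarize(result: StudyResult) -> dict:
    """JSON-serializable headline summary of a study run."""
    out = {"provenance": {k: v for k, v in result.provenance.items() if k != "sim_config"}}
    out["language_tracking"] = {
        cond: {
            "mean_delta_r": float(result.delta_language[cond].mean()),
            "min_cluster_p": min(
                (c.p_value for c in result.clusters_language[cond].clusters),
                default=1.0,
            ),
        }
        for cond in result.delta_language
    }
    out["acoustic_comparisons"] = [
        {"pair": list(pair), "W": w, "p_raw": p, "p_adj": pa}
        for pair, w, p, pa in result.acoustic_comparisons
    ]
    out["peak_counts"] = result.peak_counts()
    return out


def save_summary(result: StudyResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(summarize(result), fh, indent=2)
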