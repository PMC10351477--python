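"""Synthetic study generator: lexicon, corpus, transcripts, kernels, EEG.

The generator emulates the study design the analysis expects: three speech
conditions (a comprehensible story, a foreign story in a different lexicon
with matched timing statistics, and a shuffled word list), ~19 subjects,
64-channel EEG on the preprocessed 128 Hz grid, 455 s per condition.
Subject EEG is the convolution of the eight speech regressors with
condition-dependent ground-truth kernels (the N400-like trough to word
surprisal exists only in the comprehensible condition) plus spatially
correlated 1/f noise.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import EEGRecording, FeatureSet, Spectrogram
from .acoustic import compute_acoustic_edges
from .language import (
    Lexicon,
    NGramModel,
    impulses_from_segmentation,
    language_feature_values,
)
from .montage import positions_2d, standard_64_labels
from .segmentation import PhonemeInterval, Segmentation, WordInterval
from .trf import lag_samples, predict_eeg

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_lexicon",
    "generate_corpus",
    "generate_transcript",
    "shuffle_transcript",
    "generate_kernels",
    "generate_features",
    "simulate_eeg",
    "simulate_study",
]

CONDITIONS = ("comprehensible", "foreign", "word_list")

ACOUSTIC_FEATURES = ("spectrogram", "edges")
LEXICAL_FEATURES = ("phoneme_onsets", "word_onsets")
LANGUAGE_FEATURES = (
    "phoneme_surprisal", "cohort_entropy", "word_surprisal", "word_frequency",
)
ALL_FEATURES = ACOUSTIC_FEATURES + LEXICAL_FEATURES + LANGUAGE_FEATURES

FEATURE_FAMILY = {
    **{f: "acoustic" for f in ACOUSTIC_FEATURES},
    **{f: "lexical" for f in LEXICAL_FEATURES},
    **{f: "language" for f in LANGUAGE_FEATURES},
}


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults are the study conditions)."""

    seed: int = 0
    n_subjects: int = 19
    n_channels: int = 64
    fs: float = 128.0
    duration_s: float = 455.0
    conditions: tuple[str, ...] = CONDITIONS
    speech_rate: float = 3.5            # words / s
    lexicon_words: int = 500
    lexicon_phonemes: int = 20
    zipf_s: float = 1.1
    corpus_tokens: int = 20000
    ngram_order: int = 5
    n_acoustic_bands: int = 2
    snr_db: dict = field(default_factory=lambda: {
        "acoustic": -8.0, "lexical": -13.0, "language": -13.0,
    })
    noise_exponent: float = 1.0         # 1/f^exponent power spectrum
    jitter_sigma: float = 0.2           # lognormal per-subject amplitude jitter


@dataclass
class GroundTruth:
    """Planted kernels per condition and per-subject jitter factors."""

    kernels: dict                        # condition -> feature -> (n_arrays, L, C)
    lags: np.ndarray
    fs: float
    jitter: np.ndarray                   # (n_subjects, n_families) lognormal
    family_gains: dict                   # condition -> family -> scalar gain
    noise_exponent: float


# ---------------------------------------------------------------------------
# Lexicon / corpus / transcript
# ---------------------------------------------------------------------------

def generate_lexicon(
    seed: int,
    n_words: int = 500,
    n_phonemes: int = 20,
    zipf_s: float = 1.1,
    min_len: int = 2,
    max_len: int = 8,
    prefix_share: float = 0.6,
) -> Lexicon:
    """Random pronunciation lexicon with shared prefixes and Zipf frequencies.

    With probability ``prefix_share`` a new word reuses a random prefix of an
    existing word, so cohorts shrink gradually rather than collapsing after
    the first phoneme.  Frequencies are exactly Zipf: rank-r count
    proportional to ``(r+1)^-zipf_s``.
    """
    if n_words < 10:
        raise ValueError("need at least 10 words")
    capacity = sum(n_phonemes ** m for m in range(min_len, max_len + 1))
    if capacity < n_words:
        raise ValueError(
            f"alphabet of {n_phonemes} phonemes too small for {n_words} words"
        )
    rng = np.random.default_rng(seed)
    alphabet = [f"p{i:02d}" for i in range(n_phonemes)]
    prons: list[tuple[str, ...]] = []
    for _ in range(n_words):
        length = int(rng.integers(min_len, max_len + 1))
        if prons and rng.random() < prefix_share:
            donor = prons[int(rng.integers(len(prons)))]
            cut = int(rng.integers(1, min(len(donor), length) + 1))
            head = list(donor[:cut])
        else:
            head = []
        while len(head) < length:
            head.append(alphabet[int(rng.integers(n_phonemes))])
        prons.append(tuple(head))
    entries = {f"w{i:04d}": pron for i, pron in enumerate(prons)}
    freq = {
        f"w{i:04d}": 1000.0 * (i + 1) ** (-zipf_s) for i in range(n_words)
    }
    return Lexicon(entries=entries, freq=freq)


def generate_corpus(
    lexicon: Lexicon, seed: int, n_tokens: int = 20000,
    sentence_len: int = 12, n_successors: int = 5,
):
    """Markov word sequences over the lexicon (gives the n-gram model
    genuine context to predict).  Returns a list of sentences."""
    rng = np.random.default_rng(seed)
    words = list(lexicon.entries)
    p_uni = np.array([lexicon.freq[w] for w in words])
    p_uni = p_uni / p_uni.sum()
    successors = {
        w: rng.choice(len(words), size=n_successors, replace=False, p=p_uni)
        for w in words
    }
    sentences, sent = [], []
    current = None
    for _ in range(n_tokens):
        if current is None or rng.random() < 0.2:
            nxt = int(rng.choice(len(words), p=p_uni))
        else:
            nxt = int(rng.choice(successors[current]))
        token = words[nxt]
        sent.append(token)
        current = token
        if len(sent) >= sentence_len:
            sentences.append(sent)
            sent, current = [], None
    if sent:
        sentences.append(sent)
    return sentences


def _sample_tokens(lexicon, rng, n, successors, p_uni, words):
    out = []
    current = None
    for _ in range(n):
        if current is None or rng.random() < 0.2:
            nxt = int(rng.choice(len(words), p=p_uni))
        else:
            nxt = int(rng.choice(successors[current]))
        out.append(words[nxt])
        current = words[nxt]
    return out


def generate_transcript(
    lexicon: Lexicon,
    seed: int,
    duration_s: float,
    speech_rate: float = 3.5,
    condition: str = "comprehensible",
    tokens=None,
    fragment_id: str | None = None,
) -> tuple[Segmentation, list[str]]:
    """Timed transcript: word/phoneme segmentation plus the token sequence.

    Word tokens follow the same Markov process as :func:`generate_corpus`
    (the word-list condition passes its shuffled ``tokens`` explicitly);
    phoneme durations are Gamma distributed with a mean set so word rate
    matches ``speech_rate``, and words are separated by short exponential
    gaps.
    """
    rng = np.random.default_rng(seed)
    words = list(lexicon.entries)
    p_uni = np.array([lexicon.freq[w] for w in words])
    p_uni = p_uni / p_uni.sum()
    mean_len = float(np.dot(p_uni, [len(lexicon.entries[w]) for w in words]))
    gap_mean = 0.015
    ph_mean = (1.0 / speech_rate - gap_mean) / mean_len
    if ph_mean <= 0.02:
        raise ValueError(
            f"speech rate {speech_rate}/s incompatible with mean word length {mean_len:.1f}"
        )
    if tokens is None:
        n_est = int(duration_s * speech_rate * 1.3) + 50
        successors = {
            w: rng.choice(len(words), size=5, replace=False, p=p_uni) for w in words
        }
        tokens = _sample_tokens(lexicon, rng, n_est, successors, p_uni, words)
    word_ivs = []
    used = []
    t = float(rng.exponential(gap_mean))
    for token in tokens:
        phonemes = lexicon.entries[token]
        durations = rng.gamma(shape=2.0, scale=ph_mean / 2.0, size=len(phonemes))
        durations = np.clip(durations, 0.02, None)
        offset = t + durations.sum()
        if offset >= duration_s:
            break
        ph_ivs, pt = [], t
        for ph, d in zip(phonemes, durations):
            ph_ivs.append(PhonemeInterval(ph, pt, pt + d))
            pt += d
        word_ivs.append(WordInterval(token, t, offset, ph_ivs))
        used.append(token)
        t = offset + float(rng.exponential(gap_mean))
    if len(word_ivs) < 50:
        raise ValueError(
            f"duration {duration_s} s too short: only {len(word_ivs)} words fit"
        )
    frag = fragment_id or f"{condition}_{seed}"
    return Segmentation(words=word_ivs, fragment_id=frag), used


def shuffle_transcript(seg: Segmentation, seed: int, fragment_id: str = "word_list"):
    """Word-list transcript: shuffle the word order of a story transcript.

    Word slots (token + its phoneme durations) are permuted while the
    between-word gaps stay in place, so the word multiset and the total
    timing envelope are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seg.words))
    gaps = [seg.words[0].onset] + [
        seg.words[i + 1].onset - seg.words[i].offset for i in range(len(seg.words) - 1)
    ]
    t = 0.0
    new_words = []
    for slot, src_i in enumerate(order):
        src = seg.words[src_i]
        t += gaps[slot]
        ph_ivs, pt = [], t
        for p in src.phonemes:
            d = p.offset - p.onset
            ph_ivs.append(PhonemeInterval(p.label, pt, pt + d))
            pt += d
        new_words.append(WordInterval(src.label, t, pt, ph_ivs))
        t = pt
    tokens = [w.label for w in new_words]
    return Segmentation(words=new_words, fragment_id=fragment_id), tokens


# ---------------------------------------------------------------------------
# Ground-truth kernels
# ---------------------------------------------------------------------------

#: (center ms, width ms, amplitude, topography) per feature family.
DEFAULT_COMPONENTS = {
    "spectrogram": [(50, 20, 1.0, "frontal"), (90, 20, -0.7, "frontal"),
                    (150, 35, 0.6, "frontal")],
    "edges": [(45, 20, 1.0, "frontal"), (115, 25, -0.6, "frontal")],
    "phoneme_onsets": [(60, 25, 0.8, "frontal")],
    "word_onsets": [(70, 25, 0.8, "frontal"), (180, 40, 0.5, "frontal")],
    "phoneme_surprisal": [(250, 45, -0.8, "central")],
    "cohort_entropy": [(250, 45, -0.5, "central")],
    "word_surprisal": [(400, 50, -1.0, "central")],
    "word_frequency": [(400, 50, -0.6, "central")],
}


def _topography(name: str, labels) -> np.ndarray:
    """Smooth scalp weighting with unit maximum, centred fronto-centrally
    ('frontal') or centro-parietally ('central')."""
    pos = positions_2d(tuple(labels))
    centers = {"frontal": ("FCz",), "central": ("CPz",)}
    if name not in centers:
        raise ValueError(f"unknown topography {name!r}")
    c = positions_2d(centers[name])[0]
    d2 = ((pos - c) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2 * 0.45 ** 2))
    return topo / topo.max()


def generate_kernels(config: SimConfig) -> GroundTruth:
    """Planted TRFs: Gaussian lag components x scalp topographies.

    Acoustic and (pre)lexical kernels are identical across conditions; all
    four language-feature kernels are zeroed outside the comprehensible
    condition, planting the headline contrast (language tracking only when
    the speech can be comprehended, no acoustic-tracking difference).
    """
    labels = standard_64_labels()[: config.n_channels]
    lags = lag_samples(config.fs)
    lag_ms = lags / config.fs * 1000.0
    base = {}
    for feature, comps in DEFAULT_COMPONENTS.items():
        lagshape = np.zeros(len(lags))
        topo = None
        for center, width, amp, topo_name in comps:
            if not (lag_ms[0] <= center <= lag_ms[-1]):
                raise ValueError(
                    f"component at {center} ms outside lag window for {feature}"
                )
            lagshape = lagshape + amp * np.exp(-((lag_ms - center) ** 2) / (2 * width ** 2))
            topo = _topography(topo_name, labels)
        kern = lagshape[:, None] * topo[None, :]
        if feature in ACOUSTIC_FEATURES:
            band_w = np.linspace(1.0, 0.7, config.n_acoustic_bands)
            base[feature] = band_w[:, None, None] * kern[None, :, :]
        else:
            base[feature] = kern[None, :, :]
    kernels = {}
    for cond in config.conditions:
        kernels[cond] = {}
        for feature, kern in base.items():
            if cond != "comprehensible" and feature in LANGUAGE_FEATURES:
                kernels[cond][feature] = np.zeros_like(kern)
            else:
                kernels[cond][feature] = kern.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    jitter = rng.lognormal(
        mean=0.0, sigma=config.jitter_sigma, size=(config.n_subjects, 3)
    )
    return GroundTruth(
        kernels=kernels, lags=lags, fs=config.fs, jitter=jitter,
        family_gains={}, noise_exponent=config.noise_exponent,
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _envelope_bands(rng, n_bands: int, T: int, fs: float) -> np.ndarray:
    """Slow non-negative fluctuations standing in for spectrogram bands."""
    sos = scipy.signal.butter(2, 8.0, btype="low", fs=fs, output="sos")
    bands = np.empty((n_bands, T))
    for b in range(n_bands):
        x = scipy.signal.sosfilt(sos, rng.standard_normal(T + 256))[256:]
        bands[b] = np.abs(x)
    return bands


def generate_features(
    config: SimConfig,
    condition: str,
    seg: Segmentation,
    tokens,
    lexicon: Lexicon,
    model: NGramModel,
    seed: int,
) -> FeatureSet:
    """All eight regressors for one condition on the analysis grid.

    Impulse features come from the actual cohort-model / n-gram feature
    code, so feature collinearity (shared onset times between onsets and
    surprisal) matches the analysis assumptions by construction.
    """
    rng = np.random.default_rng(seed)
    T = int(round(config.duration_s * config.fs))
    fset = FeatureSet(fs=config.fs, n_samples=T)

    bands = _envelope_bands(rng, config.n_acoustic_bands, T, config.fs)
    spec = Spectrogram(bands.T, config.fs, np.arange(config.n_acoustic_bands) + 1.0)
    fset.add("spectrogram", bands)
    fset.add("edges", compute_acoustic_edges(spec).values.T)

    fset.add("phoneme_onsets",
             impulses_from_segmentation(seg, "phoneme", config.fs, T))
    fset.add("word_onsets",
             impulses_from_segmentation(seg, "word", config.fs, T))

    values = language_feature_values(seg, lexicon, model, tokens=tokens)
    fset.add("phoneme_surprisal",
             impulses_from_segmentation(seg, "phoneme", config.fs, T,
                                        values["phoneme_surprisal"]))
    fset.add("cohort_entropy",
             impulses_from_segmentation(seg, "phoneme", config.fs, T,
                                        values["cohort_entropy"]))
    fset.add("word_surprisal",
             impulses_from_segmentation(seg, "word", config.fs, T,
                                        values["word_surprisal"]))
    fset.add("word_frequency",
             impulses_from_segmentation(seg, "word", config.fs, T,
                                        values["word_frequency"]))
    return fset


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def one_over_f_noise(rng, n_channels: int, T: int, fs: float,
                     exponent: float = 1.0, labels=None) -> np.ndarray:
    """Spatially correlated 1/f noise, unit variance per channel.

    Independent 1/f sources are mixed through a spatially smooth random
    matrix built from electrode distances, then re-normalized per channel.
    """
    white = rng.standard_normal((n_channels, T))
    freqs = np.fft.rfftfreq(T, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    sources = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping[None, :], T, axis=1)
    sources /= sources.std(axis=1, keepdims=True)

    if labels is None:
        labels = standard_64_labels()[:n_channels]
    pos = positions_2d(tuple(labels))
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    smooth = np.exp(-d2 / (2 * 0.35 ** 2))
    mix = smooth @ rng.standard_normal((n_channels, n_channels)) / np.sqrt(n_channels)
    noise = mix @ sources
    return noise / noise.std(axis=1, keepdims=True)


def _family_signal(features: FeatureSet, kernels: dict, lags, family: str) -> np.ndarray:
    sig = None
    for feature in ALL_FEATURES:
        if FEATURE_FAMILY[feature] != family:
            continue
        contrib = predict_eeg(kernels[feature], features[feature], lags)
        sig = contrib if sig is None else sig + contrib
    return sig


def simulate_eeg(
    features: FeatureSet,
    truth: GroundTruth,
    config: SimConfig,
    condition: str,
    seed: int,
) -> list[EEGRecording]:
    """Per-subject EEG: scaled family signals + spatially correlated 1/f noise.

    Each feature family's summed contribution is scaled so its variance
    (averaged over channels) sits at the configured SNR relative to the
    unit-variance noise; per-subject lognormal jitter then multiplies the
    family amplitude.  The family gains actually used are recorded in
    ``truth.family_gains``.
    """
    labels = standard_64_labels()[: config.n_channels]
    lags = truth.lags
    kernels = truth.kernels[condition]
    families = ("acoustic", "lexical", "language")
    missing = [f for f in families if f not in config.snr_db]
    if missing:
        raise ValueError(f"snr_db missing feature families: {missing}")

    signals, gains = {}, {}
    absent_power = 0.0
    for family in families:
        sig = _family_signal(features, kernels, lags, family)
        var = float((sig ** 2).mean())
        if var > 0:
            gain = np.sqrt(10.0 ** (config.snr_db[family] / 10.0) / var)
        else:
            # a family whose kernels are zeroed in this condition (language
            # features outside the comprehensible story) still reflects
            # ongoing brain activity -- it is simply not stimulus-locked, so
            # its power moves into the noise; this keeps the total variance,
            # and hence the accuracy of the acoustic model, comparable
            # across conditions
            gain = 0.0
            absent_power += 10.0 ** (config.snr_db[family] / 10.0)
        signals[family] = sig
        gains[family] = gain
    truth.family_gains[condition] = gains
    noise_scale = np.sqrt(1.0 + absent_power)

    seeds = np.random.SeedSequence([seed]).spawn(config.n_subjects)
    recs = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(seeds[s])
        noise = one_over_f_noise(
            rng, config.n_channels, features.n_samples, config.fs,
            truth.noise_exponent, labels,
        )
        data = noise_scale * noise
        for fam_i, family in enumerate(families):
            data = data + (gains[family] * truth.jitter[s, fam_i]) * signals[family]
        recs.append(EEGRecording(
            data=data, fs=config.fs, channel_labels=labels,
            condition_id=condition, meta=[f"simulated:subject={s}"],
        ))
    return recs


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> dict:
    """Generate every input of the full study replica.

    Returns a dict with per-condition feature sets, per-condition lists of
    subject EEG recordings, transcripts/tokens, lexicons, the trained n-gram
    model, and the ground truth.
    """
    root = np.random.SeedSequence(config.seed)
    s_lex, s_corp, s_flex, s_trans, s_feat, s_eeg = [
        int(ss.generate_state(1)[0] % (2 ** 31)) for ss in root.spawn(6)
    ]
    lexicon = generate_lexicon(
        s_lex, config.lexicon_words, config.lexicon_phonemes, config.zipf_s
    )
    foreign_lexicon = generate_lexicon(
        s_flex, config.lexicon_words, config.lexicon_phonemes, config.zipf_s
    )
    corpus = generate_corpus(lexicon, s_corp, config.corpus_tokens)
    model = NGramModel(order=config.ngram_order, k=1.0).fit(corpus)
    foreign_corpus = generate_corpus(foreign_lexicon, s_corp + 1, config.corpus_tokens)
    foreign_model = NGramModel(order=config.ngram_order, k=1.0).fit(foreign_corpus)

    seg_nl, tokens_nl = generate_transcript(
        lexicon, s_trans, config.duration_s, config.speech_rate, "comprehensible"
    )
    seg_wl, tokens_wl = shuffle_transcript(seg_nl, s_trans + 1)
    seg_fr, tokens_fr = generate_transcript(
        foreign_lexicon, s_trans + 3, config.duration_s, config.speech_rate, "foreign"
    )

    per_cond = {
        "comprehensible": (seg_nl, tokens_nl, lexicon, model),
        "foreign": (seg_fr, tokens_fr, foreign_lexicon, foreign_model),
        "word_list": (seg_wl, tokens_wl, lexicon, model),
    }
    truth = generate_kernels(config)
    features, eeg = {}, {}
    for i, cond in enumerate(config.conditions):
        seg, tokens, lex, mod = per_cond[cond]
        features[cond] = generate_features(
            config, cond, seg, tokens, lex, mod, seed=s_feat + i
        )
        eeg[cond] = simulate_eeg(features[cond], truth, config, cond, seed=s_eeg + i)
    return {
        "config": config,
        "lexicon": lexicon,
        "foreign_lexicon": foreign_lexicon,
        "ngram": model,
        "segmentations": {c: per_cond[c][0] for c in config.conditions},
        "tokens": {c: per_cond[c][1] for c in config.conditions},
        "features": features,
        "eeg": eeg,
        "truth": truth,
    }
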