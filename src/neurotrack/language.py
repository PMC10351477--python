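"""Lexical prediction regressors from the cohort model and an n-gram LM.

Four language features modulate impulse amplitudes at phoneme or word onsets:

* phoneme surprisal  ``-log2( freq(cohort_i) / freq(cohort_{i-1}) )``
* cohort entropy     ``-sum_w p_w log2 p_w`` over the active cohort,
  normalized per fragment by its maximum
* word surprisal     ``-log10 p(w_i | w_{i-4}..w_{i-1})`` from a 5-gram model
* word frequency     ``-log10 p(w_i)`` from the unigram distribution

The *active cohort* after ``i`` phonemes of a word is the set of lexicon
words whose pronunciation starts with those phonemes; the cohort resets to
the whole lexicon at each word onset.  Log bases follow the convention of
bits for phoneme-level and log10 for word-level features.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

from .segmentation import Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "active_cohort",
    "phoneme_surprisal",
    "cohort_entropy",
    "normalize_entropy",
    "NGramModel",
    "train_ngram",
    "word_surprisal",
    "word_frequency",
    "impulses_from_segmentation",
    "compare_feature_distributions",
    "compare_lexicons",
]


# ---------------------------------------------------------------------------
# Lexicon and cohort model
# ---------------------------------------------------------------------------

@dataclass
class Lexicon:
    """Pronunciation dictionary with word frequencies.

    ``entries`` maps orthographic word -> phoneme tuple; ``freq`` maps word
    -> positive count.  Homophones (distinct words, identical pronunciation)
    are separate cohort members whose frequencies are not merged.
    """

    entries: dict[str, tuple[str, ...]]
    freq: dict[str, float]
    _trie: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.entries = {w: tuple(p) for w, p in self.entries.items()}
        for w, f in self.freq.items():
            if w not in self.entries:
                raise ValueError(f"word {w!r} has a frequency but no pronunciation")
            if f <= 0:
                raise ValueError(f"word {w!r}: frequency must be positive")
        missing = set(self.entries) - set(self.freq)
        if missing:
            raise ValueError(f"words without frequency: {sorted(missing)[:5]}")
        self._trie = None

    @property
    def total_freq(self) -> float:
        return sum(self.freq.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    # prefix trie caching summed frequency and member words per node
    def _build_trie(self):
        root = {"freq": 0.0, "words": [], "children": {}}
        for word, phonemes in self.entries.items():
            f = self.freq[word]
            node = root
            node["freq"] += f
            node["words"].append(word)
            for ph in phonemes:
                node = node["children"].setdefault(
                    ph, {"freq": 0.0, "words": [], "children": {}}
                )
                node["freq"] += f
                node["words"].append(word)
        self._trie = root

    def _node(self, prefix):
        if self._trie is None:
            self._build_trie()
        node = self._trie
        for ph in prefix:
            node = node["children"].get(ph)
            if node is None:
                return None
        return node

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        """Read ``word<TAB>phonemes(space separated)<TAB>frequency`` lines."""
        entries, freq = {}, {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            word, phonemes, count = line.split("\t")
            entries[word] = tuple(phonemes.split())
            freq[word] = float(count)
        return cls(entries=entries, freq=freq)

    def to_tsv(self, path) -> None:
        lines = [
            f"{w}\t{' '.join(p)}\t{self.freq[w]:g}" for w, p in self.entries.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def active_cohort(lexicon: Lexicon, prefix) -> tuple[set[str], float]:
    """Words whose pronunciation starts with ``prefix``, and their summed
    frequency.  An empty prefix returns the whole lexicon; an unmatched
    prefix returns ``(set(), 0.0)``."""
    node = lexicon._node(tuple(prefix))
    if node is None:
        return set(), 0.0
    return set(node["words"]), node["freq"]


def phoneme_surprisal(lexicon: Lexicon, word_phonemes) -> np.ndarray:
    """Per-phoneme surprisal in bits from shrinking cohort frequencies.

    ``surprisal_i = -log2(freq(cohort_i) / freq(cohort_{i-1}))`` with the
    cohort before the first phoneme being the full lexicon.
    """
    word_phonemes = tuple(word_phonemes)
    out = np.empty(len(word_phonemes))
    prev = lexicon.total_freq
    for i in range(len(word_phonemes)):
        _, f = active_cohort(lexicon, word_phonemes[: i + 1])
        if f <= 0:
            raise ValueError(
                f"cohort empty after prefix {word_phonemes[: i + 1]} (out-of-vocabulary word)"
            )
        out[i] = -math.log2(f / prev)
        prev = f
    return out


def cohort_entropy(lexicon: Lexicon, word_phonemes) -> np.ndarray:
    """Shannon entropy (bits) of the frequency-weighted active cohort after
    each phoneme, before per-fragment normalization."""
    word_phonemes = tuple(word_phonemes)
    out = np.empty(len(word_phonemes))
    for i in range(len(word_phonemes)):
        cohort, total = active_cohort(lexicon, word_phonemes[: i + 1])
        if not cohort:
            raise ValueError(
                f"cohort empty after prefix {word_phonemes[: i + 1]} (out-of-vocabulary word)"
            )
        p = np.array([lexicon.freq[w] for w in cohort]) / total
        out[i] = float(-(p * np.log2(p)).sum())
    return out


def normalize_entropy(values) -> np.ndarray:
    """Divide by the fragment-wide maximum so the largest value is 1."""
    values = np.asarray(values, dtype=float)
    m = values.max(initial=-np.inf)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("cannot normalize: no positive entropy value in fragment")
    return values / m


# ---------------------------------------------------------------------------
# n-gram language model
# ---------------------------------------------------------------------------

class NGramModel:
    """Add-k smoothed n-gram model with backoff to shorter contexts.

    For a context seen in training, ``p(w|ctx) = (c(ctx,w)+k) / (c(ctx)+k|V|)``;
    an unseen context backs off to the longest seen suffix.  With ``k == 0``
    an unseen continuation yields ``+inf`` surprisal (sentinel mode) or an
    error, selected by ``oov``.
    """

    def __init__(self, order: int = 5, k: float = 1.0, oov: str = "inf"):
        if order < 1:
            raise ValueError("order must be >= 1")
        if oov not in ("inf", "error"):
            raise ValueError("oov must be 'inf' or 'error'")
        self.order = order
        self.k = k
        self.oov = oov
        self.counts_: dict[tuple, dict[str, float]] = {}
        self.context_totals_: dict[tuple, float] = {}
        self.vocab_: set[str] = set()

    def fit(self, corpus) -> "NGramModel":
        """Count n-grams up to ``order`` from token sequences.

        ``corpus`` is an iterable of token sequences (sentences) or a single
        flat token sequence of strings.
        """
        sentences = self._as_sentences(corpus)
        if not sentences:
            raise ValueError("empty corpus")
        self.counts_ = {}
        self.vocab_ = set()
        for sent in sentences:
            sent = list(sent)
            self.vocab_.update(sent)
            for i, w in enumerate(sent):
                for n in range(self.order):
                    if i - n < 0:
                        break
                    ctx = tuple(sent[i - n:i])
                    bucket = self.counts_.setdefault(ctx, {})
                    bucket[w] = bucket.get(w, 0.0) + 1.0
        self.context_totals_ = {c: sum(b.values()) for c, b in self.counts_.items()}
        if not self.vocab_:
            raise ValueError("empty corpus")
        return self

    @staticmethod
    def _as_sentences(corpus):
        corpus = list(corpus)
        if corpus and isinstance(corpus[0], str):
            return [corpus]
        return [list(s) for s in corpus]

    def _check_fitted(self):
        if not self.vocab_:
            raise ValueError("model is not fitted")

    def prob(self, word: str, context=()) -> float:
        """``p(word | context)`` using at most ``order - 1`` context tokens."""
        self._check_fitted()
        ctx = tuple(context)[-(self.order - 1):] if self.order > 1 else ()
        V = len(self.vocab_)
        while True:
            if ctx in self.counts_:
                c_w = self.counts_[ctx].get(word, 0.0)
                total = self.context_totals_[ctx]
                num = c_w + self.k
                den = total + self.k * V
                if num > 0:
                    return num / den
                # k == 0 and unseen continuation in a seen context: back off
                # only if a shorter context can help; unigram level is final.
                if not ctx:
                    if self.oov == "error":
                        raise ValueError(f"unseen word {word!r} with k=0")
                    return 0.0
            if not ctx:
                if self.oov == "error":
                    raise ValueError(f"unseen word {word!r} with k=0")
                return 0.0
            ctx = ctx[1:]

    def unigram_prob(self, word: str) -> float:
        return self.prob(word, ())

    @classmethod
    def from_text(cls, path, order: int = 5, k: float = 1.0) -> "NGramModel":
        """Train from a UTF-8 plain-text file, whitespace tokenized, one
        sentence per line."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        sentences = [ln.split() for ln in lines if ln.split()]
        return cls(order=order, k=k).fit(sentences)


def train_ngram(corpus, order: int = 5, k: float = 1.0) -> NGramModel:
    """Functional wrapper over ``NGramModel(order, k).fit(corpus)``."""
    return NGramModel(order=order, k=k).fit(corpus)


def word_surprisal(model: NGramModel, words) -> np.ndarray:
    """``-log10 p(w_i | up to order-1 preceding words)`` per word."""
    words = list(words)
    out = np.empty(len(words))
    for i, w in enumerate(words):
        p = model.prob(w, tuple(words[max(0, i - (model.order - 1)):i]))
        out[i] = np.inf if p == 0 else -math.log10(p)
    return out


def word_frequency(model: NGramModel, words) -> np.ndarray:
    """``-log10`` unigram probability per word (higher = rarer)."""
    out = np.empty(len(words))
    for i, w in enumerate(words):
        p = model.unigram_prob(w)
        out[i] = np.inf if p == 0 else -math.log10(p)
    return out


# ---------------------------------------------------------------------------
# Impulse arrays
# ---------------------------------------------------------------------------

def impulses_from_segmentation(
    seg: Segmentation,
    level: str,
    fs: float = 128.0,
    n_samples: int | None = None,
    values=None,
) -> np.ndarray:
    """Sparse impulse array with one impulse per phoneme or word onset.

    ``values`` gives per-event amplitudes (language features); ``None`` uses
    unit amplitudes ((pre)lexical features).  Onsets are rounded
    half-away-from-zero to the nearest sample; collisions are summed with a
    warning.
    """
    if level == "word":
        onsets = seg.word_onsets
    elif level == "phoneme":
        onsets = seg.phoneme_onsets
    else:
        raise ValueError("level must be 'word' or 'phoneme'")
    if values is None:
        values = np.ones(len(onsets))
    values = np.asarray(values, dtype=float)
    if len(values) != len(onsets):
        raise ValueError(
            f"{len(values)} amplitudes for {len(onsets)} {level} onsets"
        )
    if n_samples is None:
        n_samples = int(math.floor(seg.duration * fs)) + 1
    out = np.zeros(n_samples)
    seen = set()
    for onset, amp in zip(onsets, values):
        idx = int(math.floor(onset * fs + 0.5))  # round half away from zero (onsets >= 0)
        if idx >= n_samples:
            raise ValueError(
                f"onset {onset:.3f} s maps to sample {idx} beyond T={n_samples}"
            )
        if idx in seen:
            warnings.warn(f"impulse collision at sample {idx}; amplitudes summed")
        seen.add(idx)
        out[idx] += amp
    return out


# ---------------------------------------------------------------------------
# Feature-distribution and lexicon comparisons
# ---------------------------------------------------------------------------

def compare_feature_distributions(a, b, c, labels=("a", "b", "c")):
    """Pairwise two-sample KS tests on the non-zero feature values, with
    Holm correction over the three comparisons.

    Returns a list of ``(pair, D, p_holm)`` tuples.
    """
    from .stats import holm_adjust

    samples = []
    for name, values in zip(labels, (a, b, c)):
        values = np.asarray(values, dtype=float)
        nz = values[values != 0]
        if nz.size < 2:
            raise ValueError(f"sample {name!r} has fewer than 2 non-zero values")
        samples.append(nz)
    pairs = [(0, 1), (0, 2), (1, 2)]
    stats, pvals = [], []
    for i, j in pairs:
        res = scipy.stats.ks_2samp(samples[i], samples[j])
        stats.append(res.statistic)
        pvals.append(res.pvalue)
    adj = holm_adjust(pvals)
    return [
        ((labels[i], labels[j]), float(d), float(p))
        for (i, j), d, p in zip(pairs, stats, adj)
    ]


def phoneme_position_frequencies(lexicon: Lexicon, max_position: int = 8) -> dict:
    """Frequency-weighted probability of each (phoneme, position) cell.

    Cell (ph, i) holds the probability that the i-th phoneme of a word token
    drawn by frequency is ``ph``; probabilities are normalized per position.
    """
    totals: dict[int, float] = {}
    cells: dict[tuple[str, int], float] = {}
    for word, phonemes in lexicon.entries.items():
        f = lexicon.freq[word]
        for i, ph in enumerate(phonemes[:max_position]):
            cells[(ph, i)] = cells.get((ph, i), 0.0) + f
            totals[i] = totals.get(i, 0.0) + f
    return {key: v / totals[key[1]] for key, v in cells.items()}


def compare_lexicons(lex_a: Lexicon, lex_b: Lexicon, translation: dict[str, str]):
    """Correlate two lexicons: (phoneme, position) probabilities and paired
    word frequencies under a word-to-word ``translation`` map.

    Returns ``(r_phoneme, r_word)`` Pearson correlations.
    """
    pa = phoneme_position_frequencies(lex_a)
    pb = phoneme_position_frequencies(lex_b)
    keys = sorted(set(pa) | set(pb))
    xa = np.array([pa.get(k, 0.0) for k in keys])
    xb = np.array([pb.get(k, 0.0) for k in keys])
    if len(keys) < 3:
        raise ValueError("fewer than 3 (phoneme, position) cells")
    r_ph = float(scipy.stats.pearsonr(xa, xb).statistic)

    tot_a, tot_b = lex_a.total_freq, lex_b.total_freq
    fa, fb = [], []
    for wa, wb in translation.items():
        if wa in lex_a and wb in lex_b:
            fa.append(-math.log10(lex_a.freq[wa] / tot_a))
            fb.append(-math.log10(lex_b.freq[wb] / tot_b))
    if len(fa) < 3:
        raise ValueError("fewer than 3 translated word pairs present in both lexicons")
    r_word = float(scipy.stats.pearsonr(fa, fb).statistic)
    return r_ph, r_word


def language_feature_values(
    seg: Segmentation, lexicon: Lexicon, model: NGramModel, tokens=None
):
    """Per-event feature values for one fragment.

    Returns a dict with phoneme-level arrays (one value per phoneme event;
    OOV words contribute zeros and a logged skip) and word-level arrays.
    ``tokens`` overrides the word sequence used as LM context (defaults to
    the segmentation labels).
    """
    words = [w.label for w in seg.words]
    tokens = list(tokens) if tokens is not None else words

    ph_surprisal, ph_entropy = [], []
    for w in seg.words:
        phonemes = [p.label for p in w.phonemes]
        if w.label in lexicon and tuple(phonemes) == lexicon.entries[w.label]:
            try:
                ph_surprisal.extend(phoneme_surprisal(lexicon, phonemes))
                ph_entropy.extend(cohort_entropy(lexicon, phonemes))
                continue
            except ValueError:
                pass
        logger.info("skipping OOV word %r for phoneme-level features", w.label)
        ph_surprisal.extend([0.0] * len(phonemes))
        ph_entropy.extend([0.0] * len(phonemes))

    ph_entropy = np.asarray(ph_entropy)
    if ph_entropy.max(initial=0.0) > 0:
        ph_entropy = ph_entropy / ph_entropy.max()
    return {
        "phoneme_surprisal": np.asarray(ph_surprisal),
        "cohort_entropy": ph_entropy,
        "word_surprisal": word_surprisal(model, tokens),
        "word_frequency": word_frequency(model, tokens),
    }
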