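import numpy as np
import pytest

from neurotrack.language import Lexicon
from neurotrack.preprocessing import design_ls_bandpass


@pytest.fixture()
def toy_lexicon():
    """Three-word lexicon with a shared /k/ prefix for cohort arithmetic."""
    return Lexicon(
        entries={"cat": ("k", "a", "t"), "can": ("k", "a", "n"), "dog": ("d", "o", "g")},
        freq={"cat": 10.0, "can": 5.0, "dog": 5.0},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bandpass_256():
    """The 0.5-25 Hz least-squares FIR pair at 256 Hz (design is expensive)."""
    return design_ls_bandpass(256.0)


def random_lexicon(seed, n_words=50, n_phonemes=6, max_len=5):
    """Small random lexicon with heavy prefix sharing (brute-force friendly)."""
    rng = np.random.default_rng(seed)
    alphabet = [chr(ord("a") + i) for i in range(n_phonemes)]
    entries, freq = {}, {}
    prons = []
    for i in range(n_words):
        length = int(rng.integers(2, max_len + 1))
        if prons and rng.random() < 0.7:
            donor = prons[int(rng.integers(len(prons)))]
            cut = int(rng.integers(1, min(len(donor), length) + 1))
            pron = list(donor[:cut])
        else:
            pron = []
        while len(pron) < length:
            pron.append(alphabet[int(rng.integers(n_phonemes))])
        prons.append(tuple(pron))
        entries[f"w{i}"] = tuple(pron)
        freq[f"w{i}"] = float(rng.integers(1, 100))
    return Lexicon(entries=entries, freq=freq)


def brute_force_cohort(lexicon, prefix):
    """Independent oracle: linear scan over all pronunciations."""
    prefix = tuple(prefix)
    words = {
        w for w, p in lexicon.entries.items() if p[: len(prefix)] == prefix
    }
    return words, sum(lexicon.freq[w] for w in words)
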