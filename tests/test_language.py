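"""Cohort-model features, n-gram surprisal, impulse arrays, comparisons."""

import math

import numpy as np
import pytest

from neurotrack.language import (
    Lexicon,
    NGramModel,
    active_cohort,
    cohort_entropy,
    compare_feature_distributions,
    compare_lexicons,
    impulses_from_segmentation,
    normalize_entropy,
    phoneme_surprisal,
    train_ngram,
    word_frequency,
    word_surprisal,
)
from neurotrack.segmentation import PhonemeInterval, Segmentation, WordInterval

from conftest import brute_force_cohort, random_lexicon


class TestActiveCohort:
    def test_empty_prefix_is_whole_lexicon(self, toy_lexicon):
        words, freq = active_cohort(toy_lexicon, ())
        assert words == {"cat", "can", "dog"}
        assert freq == 20.0

    def test_prefix_filters_by_pronunciation(self, toy_lexicon):
        words, freq = active_cohort(toy_lexicon, ("k",))
        assert words == {"cat", "can"}
        assert freq == 15.0

    def test_unmatched_prefix_gives_empty_cohort(self, toy_lexicon):
        words, freq = active_cohort(toy_lexicon, ("z",))
        assert words == set()
        assert freq == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_every_prefix(self, seed):
        lex = random_lexicon(seed)
        for pron in lex.entries.values():
            for i in range(len(pron) + 1):
                got = active_cohort(lex, pron[:i])
                expected = brute_force_cohort(lex, pron[:i])
                assert got[0] == expected[0]
                assert got[1] == pytest.approx(expected[1], abs=1e-12)


class TestPhonemeSurprisal:
    def test_first_phoneme_of_cat(self, toy_lexicon):
        s = phoneme_surprisal(toy_lexicon, ("k", "a", "t"))
        assert s[0] == pytest.approx(-math.log2(15 / 20))

    def test_singleton_cohort_gives_zero_onward(self, toy_lexicon):
        s = phoneme_surprisal(toy_lexicon, ("d", "o", "g"))
        # /d/ isolates dog; later phonemes add no information
        assert s[1] == pytest.approx(0.0, abs=1e-12)
        assert s[2] == pytest.approx(0.0, abs=1e-12)

    def test_halving_the_cohort_costs_one_bit(self):
        lex = Lexicon(
            entries={"aa": ("a", "a"), "ab": ("a", "b")},
            freq={"aa": 5.0, "ab": 5.0},
        )
        s = phoneme_surprisal(lex, ("a", "a"))
        assert s[1] == pytest.approx(1.0)

    def test_oov_prefix_raises_with_prefix_named(self, toy_lexicon):
        with pytest.raises(ValueError, match="out-of-vocabulary"):
            phoneme_surprisal(toy_lexicon, ("k", "z"))

    def test_nonnegative_and_chain_identity(self):
        for seed in range(20):
            lex = random_lexicon(seed)
            total = lex.total_freq
            for pron in set(lex.entries.values()):
                s = phoneme_surprisal(lex, pron)
                assert np.all(s >= -1e-12)
                _, f_full = active_cohort(lex, pron)
                assert s.sum() == pytest.approx(-math.log2(f_full / total), abs=1e-9)


class TestCohortEntropy:
    def test_equiprobable_cohort_of_four(self):
        lex = Lexicon(
            entries={f"w{i}": ("a", c) for i, c in enumerate("bcde")},
            freq={f"w{i}": 2.0 for i in range(4)},
        )
        e = cohort_entropy(lex, ("a", "b"))
        assert e[0] == pytest.approx(2.0)

    def test_singleton_cohort_zero_entropy(self, toy_lexicon):
        e = cohort_entropy(toy_lexicon, ("d",))
        assert e[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_word_cohort_hand_value(self, toy_lexicon):
        e = cohort_entropy(toy_lexicon, ("k",))
        expected = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert e[0] == pytest.approx(expected)

    def test_bounded_by_log_cohort_size(self):
        lex = random_lexicon(5)
        for pron in set(lex.entries.values()):
            e = cohort_entropy(lex, pron)
            for i in range(len(pron)):
                size = len(active_cohort(lex, pron[: i + 1])[0])
                assert e[i] <= math.log2(size) + 1e-9


class TestNormalizeEntropy:
    def test_simple_scaling(self):
        np.testing.assert_allclose(normalize_entropy([1, 2, 4]), [0.25, 0.5, 1.0])

    def test_constant_values_become_one(self):
        np.testing.assert_allclose(normalize_entropy([3.0, 3.0]), [1.0, 1.0])

    def test_algebraic_identity(self, rng):
        v = rng.random(50) + 0.1
        out = normalize_entropy(v)
        assert out.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out * v.max(), v, rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_entropy([0.0, 0.0])


class TestNGram:
    def test_deterministic_bigram(self):
        model = train_ngram("a b a b a b".split(), order=2, k=0.0)
        assert model.prob("b", ("a",)) == pytest.approx(1.0)

    def test_probabilities_normalize_over_vocab(self, rng):
        tokens = [f"t{i}" for i in rng.integers(0, 8, size=400)]
        model = train_ngram(tokens, order=3, k=1.0)
        for ctx in [(), ("t0",), ("t0", "t1"), ("nope",)]:
            total = sum(model.prob(w, ctx) for w in model.vocab_)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_unigram_ratio(self):
        tokens = ["x"] * 10 + ["y"] * 90
        model = train_ngram(tokens, order=1, k=0.0)
        assert model.unigram_prob("x") == pytest.approx(0.1)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_ngram([], order=2)

    def test_word_surprisal_values(self):
        # uniform unigram over 10 words -> log10(10) = 1 everywhere
        tokens = [f"w{i}" for i in range(10)]
        model = train_ngram(tokens, order=1, k=0.0)
        np.testing.assert_allclose(word_surprisal(model, tokens), 1.0)
        # deterministic continuation -> 0 surprisal
        model2 = train_ngram("a b a b a b".split(), order=2, k=0.0)
        assert word_surprisal(model2, ["a", "b"])[1] == pytest.approx(0.0)

    def test_quarter_probability_context(self):
        corpus = []
        for nxt in ["x", "y", "z", "q"]:
            corpus.append(["c", nxt])
        model = train_ngram(corpus, order=2, k=0.0)
        s = word_surprisal(model, ["c", "x"])
        assert s[1] == pytest.approx(-math.log10(0.25), abs=1e-12)

    def test_word_frequency_matches_counting_oracle(self, rng):
        tokens = [f"w{i}" for i in rng.integers(0, 12, size=500)]
        model = train_ngram(tokens, order=5, k=0.0)
        values = word_frequency(model, sorted(set(tokens)))
        for w, v in zip(sorted(set(tokens)), values):
            expected = -math.log10(tokens.count(w) / len(tokens))
            assert v == pytest.approx(expected, abs=1e-12)

    def test_most_frequent_word_has_minimum_value(self):
        tokens = ["a"] * 50 + ["b"] * 30 + ["c"] * 20
        model = train_ngram(tokens, order=1, k=0.0)
        values = word_frequency(model, ["a", "b", "c"])
        assert np.argmin(values) == 0


def _toy_segmentation():
    words = [
        WordInterval("cat", 0.0, 0.4, [
            PhonemeInterval("k", 0.0, 0.1),
            PhonemeInterval("a", 0.1, 0.25),
            PhonemeInterval("t", 0.25, 0.4),
        ]),
        WordInterval("dog", 0.5, 0.9, [
            PhonemeInterval("d", 0.5, 0.6),
            PhonemeInterval("o", 0.6, 0.75),
            PhonemeInterval("g", 0.75, 0.9),
        ]),
    ]
    return Segmentation(words=words, fragment_id="toy")


class TestImpulses:
    def test_word_onsets_land_on_expected_samples(self):
        seg = _toy_segmentation()
        arr = impulses_from_segmentation(seg, "word", fs=128.0, n_samples=256)
        assert arr[0] == 1.0
        assert arr[64] == 1.0
        assert np.count_nonzero(arr) == 2

    def test_event_count_conserved(self):
        seg = _toy_segmentation()
        arr = impulses_from_segmentation(seg, "phoneme", fs=128.0, n_samples=256)
        assert np.count_nonzero(arr) == 6

    def test_amplitude_sum_conserved_under_collisions(self):
        words = [WordInterval(f"w{i}", 0.001 * i, 0.001 * i + 0.0005, [])
                 for i in range(5)]
        seg = Segmentation(words=words, fragment_id="collide")
        with pytest.warns(UserWarning, match="collision"):
            arr = impulses_from_segmentation(
                seg, "word", fs=128.0, n_samples=10, values=[1, 2, 3, 4, 5]
            )
        assert arr.sum() == pytest.approx(15.0)

    def test_onset_beyond_T_rejected(self):
        seg = _toy_segmentation()
        with pytest.raises(ValueError, match="beyond"):
            impulses_from_segmentation(seg, "word", fs=128.0, n_samples=32)


class TestDistributionComparisons:
    def test_identical_samples(self, rng):
        a = rng.random(200)
        results = compare_feature_distributions(a, a.copy(), a.copy())
        for _, d, p in results:
            assert d == pytest.approx(0.0)
            assert p == pytest.approx(1.0)

    def test_disjoint_supports_give_D_one(self, rng):
        a = rng.random(100)
        b = rng.random(100) + 10.0
        c = rng.random(100) + 20.0
        results = compare_feature_distributions(a, b, c)
        for _, d, _ in results:
            assert d == pytest.approx(1.0)

    def test_only_nonzero_values_used(self, rng):
        a = np.concatenate([rng.random(100), np.zeros(500)])
        b = np.concatenate([rng.random(100), np.zeros(5)])
        (_, d, _), *_ = compare_feature_distributions(a, b, b)
        # with zeros excluded both are uniform(0,1): D should be small
        assert d < 0.25


class TestCompareLexicons:
    def test_self_comparison_is_perfect(self):
        lex = random_lexicon(3)
        identity = {w: w for w in lex.entries}
        r_ph, r_w = compare_lexicons(lex, lex, identity)
        assert r_ph == pytest.approx(1.0)
        assert r_w == pytest.approx(1.0)

    def test_independent_lexicons_nearly_uncorrelated_words(self):
        from neurotrack.simulate import generate_lexicon

        lex_a = generate_lexicon(10, n_words=1000, prefix_share=0.0)
        lex_b = generate_lexicon(11, n_words=1000, prefix_share=0.0)
        words_a = list(lex_a.entries)
        words_b = list(np.random.default_rng(0).permutation(list(lex_b.entries)))
        translation = dict(zip(words_a, words_b))
        _, r_w = compare_lexicons(lex_a, lex_b, translation)
        assert abs(r_w) < 0.1

    def test_too_few_pairs_rejected(self, toy_lexicon):
        with pytest.raises(ValueError):
            compare_lexicons(toy_lexicon, toy_lexicon, {"cat": "cat"})
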