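"""Cohort-model and segmentation predictors over phoneme timelines."""

import numpy as np
import pytest

from speechtrf import (
    NGramModel,
    cohort_predictors,
    segmentation_predictors,
    sentence_predictors,
    sentence_priors,
    sublexical_predictors,
    train_phoneme_ngram,
)
from speechtrf.errors import DataError
from speechtrf.linguistics import CohortState
from speechtrf.synth import LexiconEntry, ToyLexicon

from conftest import make_timeline


class TestCohortModel:
    def test_two_word_equal_prior_example(self, ab_lexicon):
        """AB/AC with equal priors: s(A)=0, H after A = 1 bit, s(B|A)=1 bit."""
        tl = make_timeline([("ab", ("A", "B"))])
        surp, ent = cohort_predictors(tl, ab_lexicon)
        assert surp.values[0] == pytest.approx(0.0, abs=1e-12)  # all start with A
        assert ent.values[0] == pytest.approx(1.0, abs=1e-12)  # {ab, ac} left
        assert surp.values[1] == pytest.approx(1.0, abs=1e-12)  # p(B|A) = 1/2
        assert ent.values[1] == pytest.approx(0.0, abs=1e-12)  # {ab} left

    def test_brute_force_posterior_oracle(self):
        """Cohort values equal direct Bayes enumeration over the lexicon."""
        lex = ToyLexicon(
            [
                LexiconEntry("w0", ("A", "B", "C"), 3),
                LexiconEntry("w1", ("A", "B"), 2),
                LexiconEntry("w2", ("A", "C"), 4),
                LexiconEntry("w3", ("B", "A"), 1),
            ]
        )
        tl = make_timeline([("w0", ("A", "B", "C")), ("w2", ("A", "C"))])
        surp, ent = cohort_predictors(tl, lex)
        # enumerate by hand for every phoneme position of every token
        expected_s, expected_h = [], []
        priors = {e.word: e.count / 10 for e in lex.entries}
        for word, phonemes in [("w0", ("A", "B", "C")), ("w2", ("A", "C"))]:
            active = dict(priors)
            for k, ph in enumerate(phonemes):
                match = {
                    w: p
                    for w, p in active.items()
                    if len(lex.pronunciation(w)) > k
                    and lex.pronunciation(w)[k] == ph
                }
                total = sum(active.values())
                expected_s.append(-np.log2(sum(match.values()) / total))
                post = {w: p / sum(match.values()) for w, p in match.items()}
                expected_h.append(-sum(p * np.log2(p) for p in post.values() if p > 0))
                active = match
        assert np.allclose(surp.values, expected_s, atol=1e-9)
        assert np.allclose(ent.values, expected_h, atol=1e-9)

    def test_single_word_lexicon_is_certain(self):
        lex = ToyLexicon(
            [LexiconEntry("w", ("A", "B", "A"), 5), LexiconEntry("x", ("C",), 1)]
        )
        tl = make_timeline([("w", ("A", "B", "A"))])
        surp, ent = cohort_predictors(tl, lex)
        # after the first phoneme only w remains; everything is certain
        assert np.allclose(surp.values[1:], 0.0, atol=1e-12)
        assert np.allclose(ent.values[1:], 0.0, atol=1e-12)

    def test_cohort_size_monotone_within_word(self):
        lex = ToyLexicon(
            [
                LexiconEntry(f"w{i}", p, i + 1)
                for i, p in enumerate(
                    [("A", "B"), ("A", "C"), ("A", "B", "C"), ("B", "A"), ("C",)]
                )
            ]
        )
        state = CohortState.start(lex)
        sizes = [len(state)]
        for ph in ("A", "B", "C"):
            state.consume(ph)
            sizes.append(len(state))
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_empty_cohort_error_and_uniform_fallback(self, ab_lexicon):
        tl = make_timeline([("ab", ("A", "Q"))])  # Q matches nothing
        with pytest.raises(DataError):
            cohort_predictors(tl, ab_lexicon, on_empty="error")
        with pytest.warns(UserWarning):
            surp, ent = cohort_predictors(tl, ab_lexicon, on_empty="uniform")
        # inventory {A, B, C}: uniform fallback surprisal = log2 3
        assert surp.values[1] == pytest.approx(np.log2(3))
        assert ent.values[1] == 0.0


class TestSentenceModel:
    def _four_word_lexicon(self):
        return ToyLexicon(
            [
                LexiconEntry("w0", ("A", "B"), 1),
                LexiconEntry("w1", ("A", "C"), 1),
                LexiconEntry("w2", ("B", "A"), 1),
                LexiconEntry("w3", ("C", "C"), 1),
            ]
        )

    def test_unigram_priors_reduce_to_word_form_bit_for_bit(self):
        lex = self._four_word_lexicon()
        corpus = [["w0", "w1", "w2", "w3"]]  # each word once: uniform unigram
        tl = make_timeline(
            [(w, lex.pronunciation(w)) for w in ("w2", "w0", "w3", "w1")]
        )
        unigram = NGramModel(order=1, smoothing="mle").fit(corpus)
        s_sent, h_sent = sentence_predictors(tl, lex, unigram)
        s_wf, h_wf = cohort_predictors(
            tl, lex, priors={w: 0.25 for w in lex.words}
        )
        assert np.array_equal(s_sent.values, s_wf.values)
        assert np.array_equal(h_sent.values, h_wf.values)

    def test_certain_continuation_has_zero_surprisal(self):
        lex = self._four_word_lexicon()
        # w1 always follows w0 in training
        corpus = [["w0", "w1"] for _ in range(20)] + [[w] for w in lex.words]
        lexical = NGramModel(order=5, smoothing="mle").fit(corpus)
        tl = make_timeline(
            [(w, lex.pronunciation(w)) for w in ("w0", "w1")]
        )
        s_sent, _ = sentence_predictors(tl, lex, lexical)
        # at w1's first phoneme, the prior is all on w1: surprisal 0
        assert s_sent.values[2] == pytest.approx(0.0, abs=1e-9)

    def test_priors_match_brute_force_bayes(self):
        lex = ToyLexicon(
            [LexiconEntry("x", ("A",), 1), LexiconEntry("y", ("B", "B"), 1)]
        )
        corpus = [["x", "y"], ["x", "y"], ["y", "x"]]
        lexical = NGramModel(order=2, smoothing="mle").fit(corpus)
        priors = sentence_priors(["x", "y"], lexical, lex)
        # token 0: no context -> unigram p(x)=3/6, p(y)=3/6
        assert priors[0]["x"] == pytest.approx(0.5, abs=1e-12)
        # token 1: after x, y followed twice of x's 2 continuations
        assert priors[1]["y"] == pytest.approx(1.0, abs=1e-12)

    def test_lexicon_word_missing_from_lexical_model_raises(self):
        lex = self._four_word_lexicon()
        lexical = NGramModel(order=1).fit([["w0", "w1"]])
        with pytest.raises(DataError):
            sentence_priors(["w0"], lexical, lex)


class TestSublexical:
    def test_values_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        lines = [
            [("A", "B")[j] for j in rng.integers(0, 2, 20)] for _ in range(50)
        ]
        model = train_phoneme_ngram(lines, order=3, smoothing="mle")
        tl = make_timeline([("w", tuple(lines[0][:8]))])
        surp, ent = sublexical_predictors(tl, model)
        labels = [e.phoneme for e in tl.events]
        for k in range(len(labels)):
            ctx = labels[max(0, k - 2) : k]
            assert surp.values[k] == pytest.approx(
                model.surprisal(labels[k], ctx), abs=1e-9
            )
            ectx = labels[max(0, k - 1) : k + 1]
            assert ent.values[k] == pytest.approx(model.entropy(ectx), abs=1e-9)

    def test_deterministic_model_gives_zero_everywhere(self):
        lines = [list("ABABABAB") for _ in range(5)]
        model = train_phoneme_ngram(lines, order=3, smoothing="mle")
        tl = make_timeline([("w", ("A", "B", "A", "B"))])
        surp, ent = sublexical_predictors(tl, model)
        # after the first symbol the continuation is fully determined
        assert np.allclose(surp.values[1:], 0.0, atol=1e-12)
        assert np.allclose(ent.values[1:], 0.0, atol=1e-12)


class TestSegmentation:
    def test_partition_of_phoneme_events(self, ab_lexicon):
        tl = make_timeline(
            [("ab", ("A", "B")), ("ac", ("A", "C")), ("ab", ("A", "B"))]
        )
        word, phon = segmentation_predictors(tl)
        assert len(word) == 3  # one impulse per word
        assert len(word) + len(phon) == len(tl.events)
        assert np.all(word.values == 1) and np.all(phon.values == 1)
        # no event in both series
        assert not set(word.indices) & set(phon.indices)
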