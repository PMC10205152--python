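"""Synthetic-data generators: n-back sequences, lexicons, timelines, EEG."""

import collections

import numpy as np
import pytest

import speechtrf as st
from speechtrf.errors import ConfigError, DataError
from speechtrf.basis import LagBasis
from speechtrf.synth import LexiconEntry, ToyLexicon


def rescan_targets(seq: st.VisualSequence) -> list[bool]:
    """Independent exhaustive re-derivation of target flags from loci."""
    loci = [i.locus for i in seq.items]
    flags = []
    for i in range(len(loci)):
        if seq.load == 3:
            flags.append(i >= 3 and loci[i] == loci[i - 3])
        else:
            flags.append(i >= 1 and loci[i] == loci[0])
    return flags


class TestNBack:
    def test_standard_trial_lasts_69_seconds(self):
        seq = st.generate_nback_sequence(23, 6, 3, 0.5, 2.5, seed=0)
        assert seq.total_duration == pytest.approx(69.0)
        assert len(seq.items) == 23

    @pytest.mark.parametrize("load", [0, 3])
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_flags_verified_by_exhaustive_rescan(self, load, seed):
        seq = st.generate_nback_sequence(23, 6, load, seed=seed)
        flags = rescan_targets(seq)
        assert flags == [i.is_target for i in seq.items]
        assert sum(flags) == 6
        # targets confined to the last 20 items
        assert all(i >= len(seq.items) - 20 for i, f in enumerate(flags) if f)

    def test_zero_targets(self):
        seq = st.generate_nback_sequence(23, 0, 3, seed=0)
        assert seq.n_targets == 0
        assert not any(rescan_targets(seq))

    def test_infeasible_constraints_raise(self):
        with pytest.raises(ConfigError):
            st.generate_nback_sequence(23, 21, 3, seed=0)
        with pytest.raises(ConfigError):
            st.generate_nback_sequence(5, 3, 3, seed=0)
        with pytest.raises(ConfigError):
            st.generate_nback_sequence(23, 6, 2, seed=0)

    def test_seed_determinism(self):
        a = st.generate_nback_sequence(23, 6, 3, seed=5)
        b = st.generate_nback_sequence(23, 6, 3, seed=5)
        assert a == b


class TestLexiconCorpus:
    def test_closed_vocabulary(self):
        lex, corpus = st.generate_lexicon_and_corpus(n_words=2, corpus_len=100, seed=0)
        words = set(lex.words)
        assert all(w in words for utt in corpus for w in utt)

    def test_zero_exponent_gives_uniform_frequencies(self):
        lex, corpus = st.generate_lexicon_and_corpus(
            n_words=5, corpus_len=2000, zipf_exponent=0.0, seed=1
        )
        counts = collections.Counter(w for utt in corpus for w in utt)
        total = sum(counts.values())
        freqs = np.array([counts[w] / total for w in lex.words])
        # binomial sampling error around 1/5 at ~11000 tokens
        assert np.all(np.abs(freqs - 0.2) < 4 * np.sqrt(0.2 * 0.8 / total))

    def test_counts_match_independent_recount(self):
        lex, corpus = st.generate_lexicon_and_corpus(n_words=10, corpus_len=50, seed=2)
        recount = collections.Counter(w for utt in corpus for w in utt)
        for entry in lex.entries:
            assert entry.count == max(1, recount[entry.word])

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            st.generate_lexicon_and_corpus(inventory_size=1)
        with pytest.raises(ConfigError):
            st.generate_lexicon_and_corpus(n_words=1)

    def test_lexicon_invariants_enforced(self):
        with pytest.raises(DataError):
            ToyLexicon([LexiconEntry("a", (), 1)])
        with pytest.raises(DataError):
            ToyLexicon(
                [LexiconEntry("a", ("A",), 1), LexiconEntry("a", ("B",), 1)]
            )
        with pytest.raises(DataError):
            ToyLexicon([LexiconEntry("a", ("A", "B"), 0)])


class TestTimeline:
    def test_single_word(self):
        lex = ToyLexicon([LexiconEntry("w", ("A", "B"), 1), LexiconEntry("v", ("B",), 1)])
        tl = st.timeline_from_corpus([["w"]], lex, phoneme_rate=10, seed=0)
        assert len(tl.events) == 2
        assert tl.events[0].word_initial and not tl.events[1].word_initial

    def test_duration_matches_rate(self):
        lex, corpus = st.generate_lexicon_and_corpus(n_words=8, corpus_len=20, seed=3)
        tl = st.timeline_from_corpus(corpus, lex, phoneme_rate=10, seed=3)
        n_ph = len(tl.events)
        assert tl.duration == pytest.approx(n_ph / 10, rel=0.11)

    def test_onsets_strictly_increasing_and_flags_recount(self):
        lex, corpus = st.generate_lexicon_and_corpus(n_words=8, corpus_len=20, seed=4)
        tl = st.timeline_from_corpus(corpus, lex, phoneme_rate=8, seed=4)
        onsets = [e.onset for e in tl.events]
        assert np.all(np.diff(onsets) > 0)
        # independent flag recount from lexicon pronunciations
        prons = {e.word: e.phonemes for e in lex.entries}
        expected = []
        for utt in corpus:
            for w in utt:
                expected += [True] + [False] * (len(prons[w]) - 1)
        assert expected == [e.word_initial for e in tl.events]

    def test_missing_word_raises(self):
        lex = ToyLexicon([LexiconEntry("w", ("A",), 1), LexiconEntry("v", ("B",), 1)])
        with pytest.raises(DataError):
            st.timeline_from_corpus([["nope"]], lex, seed=0)


class TestSynthesizeEEG:
    def setup_method(self):
        self.basis = LagBasis(fs=100.0)
        self.bounds = [(0, 500), (500, 1000)]
        rng = np.random.default_rng(0)
        x = np.zeros(1000)
        x[rng.choice(1000, 50, replace=False)] = 1.0
        self.x = x[None, :]
        t = self.basis.lags
        self.kernel = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)[None, :]

    def test_decomposition_is_bit_identical(self):
        eeg = st.synthesize_eeg(
            {"p": self.x}, {"p": self.kernel}, self.basis.lag_samples, 100.0,
            noise_sigma=0.7, trial_bounds=self.bounds, seed=1, n_channels=3,
        )
        assert np.array_equal(eeg.data, eeg.signal + eeg.noise)

    def test_noiseless_signal_equals_convolution_oracle(self):
        eeg = st.synthesize_eeg(
            {"p": self.x}, {"p": self.kernel}, self.basis.lag_samples, 100.0,
            noise_sigma=0.0, trial_bounds=self.bounds, seed=1, n_channels=2,
        )
        direct = st.lagged_convolve(
            self.x, self.kernel, self.basis.lag_samples, self.bounds
        )
        assert np.allclose(eeg.data, direct[None, :])

    def test_zero_kernels_give_pure_noise(self):
        eeg = st.synthesize_eeg(
            {"p": self.x}, {"p": np.zeros_like(self.kernel)},
            self.basis.lag_samples, 100.0, noise_sigma=1.0,
            trial_bounds=self.bounds, seed=2, n_channels=2,
        )
        assert np.all(eeg.signal == 0)
        assert np.array_equal(eeg.data, eeg.noise)

    def test_no_leakage_across_trials(self):
        # single impulse at the end of trial 1 must not drive trial 2
        x = np.zeros((1, 1000))
        x[0, 495] = 1.0
        eeg = st.synthesize_eeg(
            {"p": x}, {"p": self.kernel}, self.basis.lag_samples, 100.0,
            noise_sigma=0.0, trial_bounds=self.bounds, seed=0, n_channels=1,
        )
        assert np.all(eeg.data[:, 500:] == 0)

    def test_snr_zero_db_balances_variances(self):
        probe = st.synthesize_eeg(
            {"p": self.x}, {"p": self.kernel}, self.basis.lag_samples, 100.0,
            noise_sigma=0.0, trial_bounds=self.bounds, seed=0, n_channels=1,
        )
        sigma = st.noise_sigma_for_snr(probe.signal, 0.0)
        # empirical variance ratio over many noise draws
        ratios = []
        for seed in range(10):
            eeg = st.synthesize_eeg(
                {"p": self.x}, {"p": self.kernel}, self.basis.lag_samples, 100.0,
                noise_sigma=sigma, trial_bounds=self.bounds, seed=seed,
                n_channels=1,
            )
            ratios.append(np.var(eeg.signal) / np.var(eeg.noise))
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)

    def test_grid_mismatch_raises(self):
        with pytest.raises(DataError):
            st.synthesize_eeg(
                {"p": self.x, "q": np.zeros((1, 999))},
                {"p": self.kernel}, self.basis.lag_samples, 100.0, 1.0,
                self.bounds, seed=0, n_channels=1,
            )

    def test_seed_determinism(self):
        kw = dict(
            predictors={"p": self.x}, kernels={"p": self.kernel},
            lag_samples=self.basis.lag_samples, fs=100.0, noise_sigma=0.5,
            trial_bounds=self.bounds, seed=9, n_channels=2,
        )
        assert np.array_equal(st.synthesize_eeg(**kw).data, st.synthesize_eeg(**kw).data)
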