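"""Synthetic study materials with known ground truth.

Everything downstream — predictor construction, boosting TRF estimation and
the permutation statistics — can be exercised without any recorded data.
This module generates:

* toy phonological lexicons and Zipf-like corpora (stand-ins for a
  pronunciation dictionary with word-frequency counts and a training corpus),
* phoneme timelines with word boundaries (stand-in for forced alignment),
* n-back visual stimulus sequences matching the dual-task trial structure
  (23 items of 500 ms separated by 2.5 s, targets only among the last 20),
* multichannel EEG that is a sum of per-trial convolutions of known kernels
  with predictor time series plus Gaussian noise, so that estimators can be
  validated by parameter recovery.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .basis import lagged_convolve
from .errors import ConfigError, DataError

__all__ = [
    "LexiconEntry",
    "ToyLexicon",
    "PhonemeEvent",
    "PhonemeTimeline",
    "VisualItem",
    "VisualSequence",
    "SyntheticEEG",
    "generate_nback_sequence",
    "generate_lexicon_and_corpus",
    "timeline_from_corpus",
    "synthesize_eeg",
    "noise_sigma_for_snr",
]


# --------------------------------------------------------------------------
# lexicon / corpus


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    phonemes: tuple[str, ...]
    count: int


@dataclass
class ToyLexicon:
    """Pronunciation lexicon with word-frequency counts.

    Each entry is one pronunciation; a word's count mass is what drives its
    prior probability in the cohort model.  Missing words are conventionally
    given a count of 1 by the builders in this module.
    """

    entries: list[LexiconEntry]

    def __post_init__(self) -> None:
        if len({e.word for e in self.entries}) != len(self.entries):
            raise DataError("word ids must be unique")
        if any(len(e.phonemes) == 0 for e in self.entries):
            raise DataError("pronunciations must be nonempty")
        if any(e.count < 1 for e in self.entries):
            raise DataError("counts must be >= 1")
        if len(self.inventory) < 2:
            raise DataError("phoneme inventory must contain at least 2 symbols")

    @property
    def inventory(self) -> tuple[str, ...]:
        return tuple(sorted({p for e in self.entries for p in e.phonemes}))

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(e.word for e in self.entries)

    def pronunciation(self, word: str) -> tuple[str, ...]:
        for e in self.entries:
            if e.word == word:
                return e.phonemes
        raise DataError(f"word {word!r} not in lexicon")

    def priors(self) -> dict[str, float]:
        """Prior word probabilities proportional to frequency counts."""
        total = sum(e.count for e in self.entries)
        return {e.word: e.count / total for e in self.entries}


# --------------------------------------------------------------------------
# phoneme timeline


@dataclass(frozen=True)
class PhonemeEvent:
    onset: float
    phoneme: str
    word_initial: bool
    word: str
    token_index: int


@dataclass
class PhonemeTimeline:
    """Phoneme onsets with word boundaries over a continuous stimulus."""

    events: list[PhonemeEvent]
    duration: float

    def __post_init__(self) -> None:
        onsets = np.array([e.onset for e in self.events])
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise DataError("phoneme onsets must be strictly increasing")
        if onsets.size and onsets[-1] >= self.duration:
            raise DataError("all onsets must precede the total duration")

    def word_tokens(self) -> list[tuple[int, str]]:
        """(token index, word) in order of occurrence."""
        seen: list[tuple[int, str]] = []
        for e in self.events:
            if e.word_initial:
                seen.append((e.token_index, e.word))
        return seen


# --------------------------------------------------------------------------
# n-back sequences


@dataclass(frozen=True)
class VisualItem:
    onset: float
    locus: int
    is_target: bool


@dataclass
class VisualSequence:
    """One trial of the visuospatial n-back task.

    Squares appear at one of 8 loci; under the 3-back rule a target matches
    the locus three positions back, under the 0-back rule it matches the
    first item's locus.  Targets occur only among the last 20 items.
    """

    items: list[VisualItem]
    item_duration: float
    isi: float
    load: int

    @property
    def total_duration(self) -> float:
        return len(self.items) * (self.item_duration + self.isi)

    @property
    def n_targets(self) -> int:
        return sum(i.is_target for i in self.items)

    def onsets(self) -> np.ndarray:
        return np.array([i.onset for i in self.items])

    def offsets(self) -> np.ndarray:
        return self.onsets() + self.item_duration


N_LOCI = 8
TARGET_WINDOW = 20  # targets restricted to the last 20 items


def generate_nback_sequence(
    n_items: int = 23,
    n_targets: int = 6,
    load: int = 3,
    item_duration: float = 0.5,
    isi: float = 2.5,
    seed: int | np.random.Generator = 0,
) -> VisualSequence:
    """Generate one n-back trial with exactly ``n_targets`` targets.

    The load rule holds at every flagged position and fails at every
    unflagged position from the rule's first applicable index onward
    (index 3 for 3-back, index 1 for 0-back).
    """
    if load not in (0, 3):
        raise ConfigError("load must be 0 or 3")
    rng = np.random.default_rng(seed)
    first_applicable = 3 if load == 3 else 1
    eligible = [
        i for i in range(n_items) if i >= max(first_applicable, n_items - TARGET_WINDOW)
    ]
    if n_targets > len(eligible):
        raise ConfigError(
            f"cannot place {n_targets} targets among {len(eligible)} eligible "
            f"positions (last {TARGET_WINDOW} items, index >= {first_applicable})"
        )
    target_idx = set(rng.choice(eligible, size=n_targets, replace=False).tolist())

    loci: list[int] = []
    for i in range(n_items):
        required = None
        if load == 3 and i >= 3:
            required = loci[i - 3]
        elif load == 0 and i >= 1:
            required = loci[0]
        if required is None:
            loci.append(int(rng.integers(1, N_LOCI + 1)))
        elif i in target_idx:
            loci.append(required)
        else:
            others = [l for l in range(1, N_LOCI + 1) if l != required]
            loci.append(int(rng.choice(others)))

    soa = item_duration + isi
    items = [
        VisualItem(onset=i * soa, locus=loci[i], is_target=i in target_idx)
        for i in range(n_items)
    ]
    return VisualSequence(items=items, item_duration=item_duration, isi=isi, load=load)


# --------------------------------------------------------------------------
# lexicon + corpus generation

_PHONEME_SYMBOLS = tuple(string.ascii_uppercase)


def generate_lexicon_and_corpus(
    inventory_size: int = 6,
    n_words: int = 20,
    corpus_len: int = 200,
    zipf_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    min_word_len: int = 2,
    max_word_len: int = 5,
    utterance_len: tuple[int, int] = (3, 8),
) -> tuple[ToyLexicon, list[list[str]]]:
    """Random lexicon plus a corpus of utterances with Zipf-like frequencies.

    Word pronunciations are distinct random strings over an inventory of
    ``inventory_size`` symbols; corpus tokens are drawn with probability
    proportional to ``rank ** -zipf_exponent`` (exponent 0 gives a uniform
    vocabulary).  Lexicon counts are the realised corpus token counts, with
    a count of 1 substituted for words that never occur.
    """
    if inventory_size < 2:
        raise ConfigError("inventory_size must be >= 2")
    if n_words < 2:
        raise ConfigError("n_words must be >= 2")
    if inventory_size > len(_PHONEME_SYMBOLS):
        raise ConfigError(f"inventory_size capped at {len(_PHONEME_SYMBOLS)}")
    rng = np.random.default_rng(seed)
    inventory = _PHONEME_SYMBOLS[:inventory_size]

    prons: set[tuple[str, ...]] = set()
    attempts = 0
    while len(prons) < n_words:
        attempts += 1
        if attempts > 1000 * n_words:
            raise ConfigError("inventory too small for the requested vocabulary")
        length = int(rng.integers(min_word_len, max_word_len + 1))
        prons.add(tuple(rng.choice(inventory, size=length).tolist()))
    pron_list = sorted(prons)
    rng.shuffle(pron_list)
    words = [f"w{i:03d}" for i in range(n_words)]

    ranks = np.arange(1, n_words + 1, dtype=float)
    p = ranks ** -float(zipf_exponent)
    p /= p.sum()

    corpus: list[list[str]] = []
    for _ in range(corpus_len):
        n_tok = int(rng.integers(utterance_len[0], utterance_len[1] + 1))
        corpus.append([words[j] for j in rng.choice(n_words, size=n_tok, p=p)])

    counts = {w: 0 for w in words}
    for utt in corpus:
        for w in utt:
            counts[w] += 1
    entries = [
        LexiconEntry(word=w, phonemes=pron_list[i], count=max(1, counts[w]))
        for i, w in enumerate(words)
    ]
    return ToyLexicon(entries=entries), corpus


def timeline_from_corpus(
    corpus: list[list[str]],
    lexicon: ToyLexicon,
    phoneme_rate: float = 8.0,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.1,
) -> PhonemeTimeline:
    """Synthetic forced alignment: phonemes at ~``phoneme_rate``/s with jitter.

    Inter-phoneme intervals are ``1/rate`` scaled by a uniform factor in
    ``1 +/- jitter``, so onsets stay strictly increasing.
    """
    if phoneme_rate <= 0:
        raise ConfigError("phoneme_rate must be positive")
    rng = np.random.default_rng(seed)
    prons = {e.word: e.phonemes for e in lexicon.entries}
    base = 1.0 / phoneme_rate
    events: list[PhonemeEvent] = []
    t = 0.0
    token = 0
    for utt in corpus:
        for word in utt:
            if word not in prons:
                raise DataError(f"word {word!r} has no pronunciation in the lexicon")
            for k, ph in enumerate(prons[word]):
                events.append(
                    PhonemeEvent(
                        onset=t,
                        phoneme=ph,
                        word_initial=(k == 0),
                        word=word,
                        token_index=token,
                    )
                )
                t += base * (1.0 + jitter * float(rng.uniform(-1, 1)))
            token += 1
    return PhonemeTimeline(events=events, duration=t + base)


# --------------------------------------------------------------------------
# synthetic EEG


@dataclass
class SyntheticEEG:
    """Trial-structured EEG built from known kernels plus Gaussian noise.

    ``data`` is bit-identical to ``signal + noise``; ``kernels`` maps each
    predictor name to its ground-truth ``(n_dims, n_lags, n_channels)`` lag
    functions on ``lag_samples`` (at ``fs``).
    """

    data: np.ndarray
    signal: np.ndarray
    noise: np.ndarray
    fs: float
    trial_bounds: list[tuple[int, int]]
    kernels: dict[str, np.ndarray]
    lag_samples: np.ndarray
    noise_sigma: float
    seed: int | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.shape != self.signal.shape or self.data.shape != self.noise.shape:
            raise DataError("data, signal and noise must share a shape")
        if self.trial_bounds and self.trial_bounds[-1][1] != self.data.shape[1]:
            raise DataError("trial bounds inconsistent with data length")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def synthesize_eeg(
    predictors: dict[str, np.ndarray],
    kernels: dict[str, np.ndarray],
    lag_samples: np.ndarray,
    fs: float,
    noise_sigma: float,
    trial_bounds: list[tuple[int, int]],
    seed: int | np.random.Generator = 0,
    n_channels: int | None = None,
) -> SyntheticEEG:
    """EEG = sum over predictors of (kernel (*) predictor) + Gaussian noise.

    Convolution respects trial boundaries (no leakage).  Kernels may be
    ``(n_dims, n_lags)`` (shared across channels) or
    ``(n_dims, n_lags, n_channels)``.
    """
    if set(kernels) - set(predictors):
        raise DataError(f"kernels without predictors: {set(kernels) - set(predictors)}")
    lengths = {np.atleast_2d(x).shape[1] for x in predictors.values()}
    if len(lengths) > 1:
        raise DataError(f"predictors disagree on grid length: {sorted(lengths)}")
    n_samples = lengths.pop() if lengths else 0

    # infer channel count
    chans = {k.shape[2] for k in kernels.values() if np.asarray(k).ndim == 3}
    if n_channels is None:
        if not chans:
            raise ConfigError("n_channels required when all kernels are 2-D")
        n_channels = chans.pop()
    full_kernels: dict[str, np.ndarray] = {}
    signal = np.zeros((n_channels, n_samples))
    for name, k in kernels.items():
        k = np.asarray(k, dtype=float)
        if k.ndim == 2:
            k = np.repeat(k[:, :, None], n_channels, axis=2)
        if k.shape[2] != n_channels:
            raise DataError(f"kernel {name!r} has {k.shape[2]} channels, "
                            f"expected {n_channels}")
        full_kernels[name] = k
        signal += lagged_convolve(
            predictors[name], k, lag_samples, trial_bounds
        )

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.shape) * noise_sigma
    return SyntheticEEG(
        data=signal + noise,
        signal=signal,
        noise=noise,
        fs=fs,
        trial_bounds=list(trial_bounds),
        kernels=full_kernels,
        lag_samples=np.asarray(lag_samples),
        noise_sigma=noise_sigma,
        seed=seed if isinstance(seed, int) else None,
    )


def noise_sigma_for_snr(signal: np.ndarray, snr_db: float) -> float:
    """Noise standard deviation giving the requested signal-to-noise ratio.

    SNR is the variance ratio of the (zero-mean) signal part to the noise
    part, in dB: ``10 * log10(var(signal) / sigma**2)``.
    """
    var_signal = float(np.var(signal))
    if var_signal == 0:
        raise DataError("signal has zero variance; SNR undefined")
    return float(np.sqrt(var_signal / (10.0 ** (snr_db / 10.0))))
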