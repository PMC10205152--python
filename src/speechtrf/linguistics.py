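"""Information-theoretic linguistic predictors.

Three predictive contexts of increasing span, each yielding a surprisal and
an entropy impulse predictor with one event per phoneme onset:

* **sublexical** — a phoneme 5-gram model: the upcoming phoneme is predicted
  from the 4 preceding phonemes, ignoring word boundaries;
* **word form** — the cohort model: within each word the lexicon is pruned
  phoneme by phoneme, starting from frequency-based prior word
  probabilities, with no access to context before the word;
* **sentence** — the same cohort procedure, but the prior for each word
  token is set from a lexical 5-gram model conditioned on the preceding
  four words.

Two unit-impulse segmentation predictors (word onset / phoneme onset)
control for responses to boundaries as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ImpulseSeries
from .errors import ConfigError, DataError
from .ngram import NGramModel
from .synth import PhonemeTimeline, ToyLexicon

__all__ = [
    "CohortState",
    "sublexical_predictors",
    "cohort_predictors",
    "sentence_priors",
    "sentence_predictors",
    "segmentation_predictors",
]

PREDICTOR_FS = 1000.0


# ---------------------------------------------------------------------------
# cohort model


@dataclass
class CohortState:
    """Probability distribution over a lexicon, pruned phoneme by phoneme.

    ``probs`` maps lexicon words to posterior probabilities given the
    phonemes consumed so far within the current word; it always sums to 1
    over the active set while the cohort is nonempty.
    """

    probs: dict[str, float]
    prons: dict[str, tuple[str, ...]]
    consumed: int = 0

    @classmethod
    def start(
        cls, lexicon: ToyLexicon, priors: dict[str, float] | None = None
    ) -> "CohortState":
        """Fresh cohort over the full lexicon with (normalized) priors."""
        if priors is None:
            priors = lexicon.priors()
        missing = set(lexicon.words) - set(priors)
        if missing:
            raise DataError(f"priors missing for words: {sorted(missing)[:5]}")
        total = sum(priors[w] for w in lexicon.words)
        if total <= 0:
            raise DataError("priors sum to zero over the lexicon")
        return cls(
            probs={w: priors[w] / total for w in lexicon.words},
            prons={e.word: e.phonemes for e in lexicon.entries},
        )

    @property
    def entropy(self) -> float:
        """Shannon entropy (bits) over the words currently in the cohort."""
        p = np.array([v for v in self.probs.values() if v > 0])
        if p.size == 0:
            return 0.0
        return float(-(p * np.log2(p)).sum())

    def phoneme_probability(self, phoneme: str) -> float:
        """P(next phoneme = ``phoneme``) under the current cohort."""
        k = self.consumed
        return sum(
            p
            for w, p in self.probs.items()
            if len(self.prons[w]) > k and self.prons[w][k] == phoneme
        )

    def consume(self, phoneme: str) -> float:
        """Advance by one phoneme; returns its probability before pruning.

        Words whose pronunciation does not have ``phoneme`` at the current
        position are removed and the remaining probabilities renormalized.
        Returns 0.0 (and empties the cohort) when nothing is compatible.
        """
        k = self.consumed
        p_ph = self.phoneme_probability(phoneme)
        survivors = {
            w: p
            for w, p in self.probs.items()
            if len(self.prons[w]) > k and self.prons[w][k] == phoneme
        }
        total = sum(survivors.values())
        if total > 0:
            self.probs = {w: p / total for w, p in survivors.items()}
        else:
            self.probs = {}
        self.consumed = k + 1
        return p_ph

    def __len__(self) -> int:
        return len(self.probs)


def _grouped_events(timeline: PhonemeTimeline):
    """Yield (token_index, word, [events]) per word token, in order."""
    groups: list[tuple[int, str, list]] = []
    for e in timeline.events:
        if e.word_initial:
            groups.append((e.token_index, e.word, [e]))
        else:
            if not groups or groups[-1][0] != e.token_index:
                raise DataError("timeline has a non-initial phoneme starting a word")
            groups[-1][2].append(e)
    return groups


# ---------------------------------------------------------------------------
# predictor construction


def sublexical_predictors(
    timeline: PhonemeTimeline,
    model: NGramModel,
    fs: float = PREDICTOR_FS,
) -> tuple[ImpulseSeries, ImpulseSeries]:
    """Sublexical surprisal and entropy impulses at each phoneme onset.

    Surprisal of phoneme *k* is ``-log2 p(ph_k | 4 preceding phonemes)``;
    entropy at *k* is the Shannon entropy of the model's distribution for
    the *next* phoneme given the context ending at *k*.  The context spans
    word boundaries (the sublexical model never sees them).
    """
    labels = [e.phoneme for e in timeline.events]
    times = [e.onset for e in timeline.events]
    surp = np.empty(len(labels))
    ent = np.empty(len(labels))
    for k, ph in enumerate(labels):
        context = labels[max(0, k - (model.order - 1)) : k]
        surp[k] = model.surprisal(ph, context)
        ent[k] = model.entropy(labels[max(0, k - (model.order - 2)) : k + 1])
    kw = dict(fs=fs, duration=timeline.duration)
    return (
        ImpulseSeries.from_times(times, surp, name="sublexical_surprisal", **kw),
        ImpulseSeries.from_times(times, ent, name="sublexical_entropy", **kw),
    )


def cohort_predictors(
    timeline: PhonemeTimeline,
    lexicon: ToyLexicon,
    priors: dict[str, float] | list[dict[str, float]] | None = None,
    fs: float = PREDICTOR_FS,
    on_empty: str = "error",
    name_prefix: str = "wordform",
) -> tuple[ImpulseSeries, ImpulseSeries]:
    """Cohort-model phoneme surprisal and cohort entropy impulses.

    At each word onset the cohort resets to the full lexicon with the prior
    probabilities (a single dict shared by all tokens, or one dict per word
    token for sentence-conditioned priors).  Phoneme surprisal is
    ``-log2`` of the summed probability of cohort members matching the
    phoneme at its position; cohort entropy is the Shannon entropy over the
    pruned, renormalized cohort.

    ``on_empty`` controls cohort die-off (a phoneme matching no entry):
    ``"error"`` raises; ``"uniform"`` restarts scoring from a uniform
    distribution over the phoneme inventory for the rest of the word.
    """
    if on_empty not in ("error", "uniform"):
        raise ConfigError(f"on_empty must be 'error' or 'uniform', got {on_empty!r}")
    groups = _grouped_events(timeline)
    if isinstance(priors, list):
        if len(priors) != len(groups):
            raise DataError(
                f"{len(priors)} prior distributions for {len(groups)} word tokens"
            )
        per_token = priors
    else:
        per_token = [priors] * len(groups)

    inventory_size = len(lexicon.inventory)
    times: list[float] = []
    surp: list[float] = []
    ent: list[float] = []
    for (token, word, events), prior in zip(groups, per_token):
        state = CohortState.start(lexicon, prior)
        dead = False
        for e in events:
            times.append(e.onset)
            if dead:
                surp.append(float(np.log2(inventory_size)))
                ent.append(0.0)
                continue
            p_ph = state.consume(e.phoneme)
            if p_ph <= 0 or len(state) == 0:
                if on_empty == "error":
                    raise DataError(
                        f"cohort emptied at phoneme {e.phoneme!r} of word "
                        f"token {token} ({word!r})"
                    )
                warnings.warn(
                    f"cohort emptied in word token {token} ({word!r}); "
                    "falling back to uniform phoneme scoring",
                    stacklevel=2,
                )
                dead = True
                surp.append(float(np.log2(inventory_size)))
                ent.append(0.0)
            else:
                surp.append(float(-np.log2(p_ph)))
                ent.append(state.entropy)
    kw = dict(fs=fs, duration=timeline.duration)
    return (
        ImpulseSeries.from_times(times, surp, name=f"{name_prefix}_surprisal", **kw),
        ImpulseSeries.from_times(times, ent, name=f"{name_prefix}_entropy", **kw),
    )


def sentence_priors(
    word_tokens: list[str],
    lexical_model: NGramModel,
    lexicon: ToyLexicon,
    utterance_breaks: list[int] | None = None,
) -> list[dict[str, float]]:
    """Per-token prior word distributions from a lexical n-gram model.

    The prior for token *j* is proportional to the lexical model's
    probability of each lexicon word given the preceding four words.
    ``utterance_breaks`` lists token indices that start a new utterance;
    context does not cross those boundaries.
    """
    breaks = set(utterance_breaks or [0])
    vocab_idx = {w: i for i, w in enumerate(lexical_model.vocab)}
    missing = [w for w in lexicon.words if w not in vocab_idx]
    if missing:
        raise DataError(
            f"lexicon words absent from the lexical model: {missing[:5]}"
        )
    priors: list[dict[str, float]] = []
    start = 0
    for j in range(len(word_tokens)):
        if j in breaks:
            start = j
        context = word_tokens[max(start, j - (lexical_model.order - 1)) : j]
        dist = lexical_model.dist(context)
        raw = {w: float(dist[vocab_idx[w]]) for w in lexicon.words}
        total = sum(raw.values())
        if total <= 0:
            raise DataError(f"lexical model gives zero mass to the lexicon at token {j}")
        priors.append({w: p / total for w, p in raw.items()})
    return priors


def sentence_predictors(
    timeline: PhonemeTimeline,
    lexicon: ToyLexicon,
    lexical_model: NGramModel,
    fs: float = PREDICTOR_FS,
    on_empty: str = "error",
    utterance_breaks: list[int] | None = None,
) -> tuple[ImpulseSeries, ImpulseSeries]:
    """Sentence-level cohort predictors: word priors follow the word context."""
    tokens = [w for _, w in timeline.word_tokens()]
    priors = sentence_priors(tokens, lexical_model, lexicon, utterance_breaks)
    return cohort_predictors(
        timeline, lexicon, priors, fs=fs, on_empty=on_empty, name_prefix="sentence"
    )


def segmentation_predictors(
    timeline: PhonemeTimeline,
    fs: float = PREDICTOR_FS,
) -> tuple[ImpulseSeries, ImpulseSeries]:
    """Unit impulses at word-initial phonemes and at all other phonemes.

    The two series partition the phoneme events: every event appears in
    exactly one of them, always with value 1.
    """
    w_times = [e.onset for e in timeline.events if e.word_initial]
    p_times = [e.onset for e in timeline.events if not e.word_initial]
    kw = dict(fs=fs, duration=timeline.duration)
    return (
        ImpulseSeries.from_times(w_times, np.ones(len(w_times)), name="word_onset", **kw),
        ImpulseSeries.from_times(p_times, np.ones(len(p_times)), name="phoneme_onset", **kw),
    )
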