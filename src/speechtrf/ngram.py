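"""N-gram sequence models over phonemes or words.

Supports two estimation modes:

``mle``
    Unsmoothed relative frequencies with backoff to the longest observed
    suffix context (uniform over the vocabulary as last resort).  This is the
    mode the enumeration oracles in the test-suite check against, since its
    probabilities are exactly count ratios.

``kneser_ney``
    Interpolated Kneser-Ney with a fixed absolute discount: raw counts at
    the highest order, continuation counts below, and a final interpolation
    with the uniform distribution so every vocabulary symbol has nonzero
    probability in any context.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["NGramModel", "train_phoneme_ngram"]

Context = tuple[str, ...]


@dataclass
class NGramModel:
    """Backoff/interpolated n-gram model of symbol sequences."""

    order: int = 5
    smoothing: str = "mle"
    discount: float = 0.75
    vocab: tuple[str, ...] = ()
    # raw counts per context length 0..order-1: counts[k][context][symbol]
    _counts: list[dict] = field(default_factory=list, repr=False)
    _totals: list[dict] = field(default_factory=list, repr=False)
    # continuation counts for Kneser-Ney lower orders
    _cont: list[dict] = field(default_factory=list, repr=False)
    _cont_totals: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigError("order must be >= 1")
        if self.smoothing not in ("mle", "kneser_ney"):
            raise ConfigError(f"unknown smoothing {self.smoothing!r}")

    # ------------------------------------------------------------------
    def fit(self, sequences: Iterable[Sequence[str]]) -> "NGramModel":
        """Count all n-grams of order 1..`order` in the training sequences."""
        counts = [defaultdict(lambda: defaultdict(int)) for _ in range(self.order)]
        vocab: set[str] = set()
        n_seq = 0
        for seq in sequences:
            seq = tuple(seq)
            if seq:
                n_seq += 1
            vocab.update(seq)
            for i, sym in enumerate(seq):
                for k in range(min(i, self.order - 1) + 1):
                    counts[k][seq[i - k : i]][sym] += 1
        if n_seq == 0:
            raise DataError("training corpus is empty")
        self.vocab = tuple(sorted(vocab))
        self._counts = [dict(c) for c in counts]
        self._totals = [
            {ctx: sum(d.values()) for ctx, d in level.items()} for level in self._counts
        ]
        self._build_continuation()
        return self

    def _build_continuation(self) -> None:
        # cont[k][context][symbol] = number of distinct symbols x such that
        # the (k+2)-gram (x, *context, symbol) was observed
        self._cont = [defaultdict(lambda: defaultdict(int)) for _ in range(self.order)]
        for k in range(1, self.order):
            for ctx, d in self._counts[k].items():
                lower = ctx[1:]
                for sym in d:
                    self._cont[len(lower)][lower][sym] += 1
        self._cont = [
            {ctx: dict(d) for ctx, d in level.items()} for level in self._cont
        ]
        self._cont_totals = [
            {ctx: sum(d.values()) for ctx, d in level.items()} for level in self._cont
        ]

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not self.vocab:
            raise DataError("model has not been fitted")

    def _mle_dist(self, context: Context) -> np.ndarray:
        v = len(self.vocab)
        idx = {s: i for i, s in enumerate(self.vocab)}
        for k in range(min(len(context), self.order - 1), -1, -1):
            ctx = context[len(context) - k :]
            if ctx in self._counts[k]:
                p = np.zeros(v)
                for sym, c in self._counts[k][ctx].items():
                    p[idx[sym]] = c
                return p / p.sum()
        return np.full(v, 1.0 / v)

    def _kn_dist(self, context: Context) -> np.ndarray:
        v = len(self.vocab)
        idx = {s: i for i, s in enumerate(self.vocab)}
        d = self.discount
        # base: uniform
        p = np.full(v, 1.0 / v)
        # unigram continuation level (k=0)
        levels = []
        for k in range(min(len(context), self.order - 1) + 1):
            levels.append(context[len(context) - k :] if k else ())
        for k, ctx in enumerate(levels):
            top = k == self.order - 1
            table = self._counts[k] if top else self._cont[k]
            totals = self._totals[k] if top else self._cont_totals[k]
            if ctx not in table or totals.get(ctx, 0) == 0:
                continue  # back off: keep the lower-order distribution
            total = totals[ctx]
            row = table[ctx]
            new = np.zeros(v)
            for sym, c in row.items():
                new[idx[sym]] = max(c - d, 0.0)
            new /= total
            lam = d * len(row) / total
            p = new + lam * p
        return p

    def dist(self, context: Sequence[str]) -> np.ndarray:
        """Conditional distribution over the vocabulary given a context.

        Only the trailing ``order - 1`` symbols of the context are used.
        """
        self._check_fitted()
        context = tuple(context)[-(self.order - 1) :] if self.order > 1 else ()
        if self.smoothing == "mle":
            return self._mle_dist(context)
        return self._kn_dist(context)

    def prob(self, symbol: str, context: Sequence[str]) -> float:
        self._check_fitted()
        if symbol not in self.vocab:
            raise DataError(f"symbol {symbol!r} not in model vocabulary")
        return float(self.dist(context)[self.vocab.index(symbol)])

    def surprisal(self, symbol: str, context: Sequence[str]) -> float:
        """Information content of ``symbol`` in ``context``, in bits."""
        p = self.prob(symbol, context)
        if p <= 0:
            raise DataError(
                f"zero probability for {symbol!r} in unsmoothed model; "
                "use kneser_ney smoothing or a closed-vocabulary corpus"
            )
        return float(-np.log2(p))

    def entropy(self, context: Sequence[str]) -> float:
        """Shannon entropy of the next-symbol distribution, in bits."""
        p = self.dist(context)
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())


def train_phoneme_ngram(
    phoneme_lines: Iterable[Sequence[str]],
    order: int = 5,
    smoothing: str = "mle",
    discount: float = 0.75,
) -> NGramModel:
    """Train a phoneme n-gram model on utterance phoneme sequences.

    Each line is one utterance's phoneme sequence *without word-boundary
    markers* (the sublexical model's context deliberately spans word
    boundaries).
    """
    model = NGramModel(order=order, smoothing=smoothing, discount=discount)
    return model.fit(phoneme_lines)
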