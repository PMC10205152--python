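import numpy as np
import pytest

from speechtrf import LagBasis, ToyLexicon
from speechtrf.synth import LexiconEntry, PhonemeEvent, PhonemeTimeline


@pytest.fixture(scope="session")
def basis100() -> LagBasis:
    """Standard basis: 50 ms Hamming windows, lags -100..500 ms at 100 Hz."""
    return LagBasis(fs=100.0)


@pytest.fixture()
def ab_lexicon() -> ToyLexicon:
    """Two equiprobable words sharing a first phoneme: AB and AC."""
    return ToyLexicon(
        entries=[
            LexiconEntry("ab", ("A", "B"), 1),
            LexiconEntry("ac", ("A", "C"), 1),
        ]
    )


def make_timeline(words: list[tuple[str, tuple[str, ...]]], dt: float = 0.1):
    """Timeline with evenly spaced phonemes from (word, pronunciation) pairs."""
    events = []
    t = 0.0
    for token, (word, phonemes) in enumerate(words):
        for k, ph in enumerate(phonemes):
            events.append(
                PhonemeEvent(
                    onset=t, phoneme=ph, word_initial=(k == 0), word=word,
                    token_index=token,
                )
            )
            t += dt
    return PhonemeTimeline(events=events, duration=t + dt)


@pytest.fixture()
def impulse_predictor():
    """Sparse positive impulse train on a trial grid, for TRF simulations."""

    def _make(T: int, n_events: int, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(T)
        idx = rng.choice(T, size=n_events, replace=False)
        x[idx] = rng.uniform(0.5, 2.0, size=n_events)
        return x

    return _make
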