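"""File formats: Praat TextGrid, TSV lexicons, binary array containers.

The native array container is flat little-endian float64 binary
(channel x time, C order) plus a JSON sidecar carrying shape, sampling rate
and labels.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from pathlib import Path

import numpy as np

from .containers import ImpulseSeries, Spectrogram
from .errors import DataError
from .synth import LexiconEntry, PhonemeEvent, PhonemeTimeline, ToyLexicon

__all__ = [
    "atomic_write_bytes",
    "atomic_write_text",
    "write_textgrid",
    "read_textgrid",
    "write_lexicon",
    "read_lexicon",
    "save_array",
    "load_array",
    "save_impulse_series",
    "load_impulse_series",
    "save_spectrogram",
    "load_spectrogram",
]


def atomic_write_bytes(path: Path | str, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path | str, text: str) -> None:
    atomic_write_bytes(path, text.encode())


# ---------------------------------------------------------------------------
# TextGrid (Praat long text format), phone + word interval tiers


def write_textgrid(path: Path | str, timeline: PhonemeTimeline) -> None:
    events = timeline.events
    phones = []
    for i, e in enumerate(events):
        end = events[i + 1].onset if i + 1 < len(events) else timeline.duration
        phones.append((e.onset, end, e.phoneme))
    words = []
    for i, e in enumerate(events):
        if not e.word_initial:
            continue
        j = i + 1
        while j < len(events) and not events[j].word_initial:
            j += 1
        end = events[j].onset if j < len(events) else timeline.duration
        words.append((e.onset, end, e.word))

    def tier(name, intervals):
        out = [
            f'        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {timeline.duration!r}",
            f"        intervals: size = {len(intervals)}",
        ]
        for k, (a, b, label) in enumerate(intervals, 1):
            out += [
                f"        intervals [{k}]:",
                f"            xmin = {a!r}",
                f"            xmax = {b!r}",
                f'            text = "{label}"',
            ]
        return out

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {timeline.duration!r}",
        "tiers? <exists>",
        "size = 2",
        "item []:",
        "    item [1]:",
        *tier("phones", phones),
        "    item [2]:",
        *tier("words", words),
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


_TG_INTERVAL = re.compile(
    r"intervals \[\d+\]:\s*xmin = ([\d.eE+-]+)\s*xmax = ([\d.eE+-]+)"
    r'\s*text = "([^"]*)"'
)


def read_textgrid(path: Path | str) -> PhonemeTimeline:
    """Read a phone+word TextGrid back into a timeline.

    Word-initial flags are recovered by matching phone onsets against word
    interval onsets (1 microsecond tolerance).
    """
    text = Path(path).read_text()
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    chunks = re.split(r'name = "([^"]+)"', text)
    xmax = re.search(r"xmax = ([\d.eE+-]+)", text)
    if xmax is None:
        raise DataError(f"{path}: not a TextGrid")
    for name, chunk in zip(chunks[1::2], chunks[2::2]):
        tiers[name] = [
            (float(a), float(b), lab) for a, b, lab in _TG_INTERVAL.findall(chunk)
        ]
    if "phones" not in tiers or "words" not in tiers:
        raise DataError(f"{path}: expected 'phones' and 'words' tiers")
    word_starts = [(a, lab) for a, _, lab in tiers["words"] if lab]
    events = []
    token = -1
    word = ""
    w_iter = iter(word_starts)
    next_word = next(w_iter, None)
    for a, _, ph in tiers["phones"]:
        if not ph:
            continue
        initial = next_word is not None and abs(a - next_word[0]) < 1e-6
        if initial:
            token += 1
            word = next_word[1]
            next_word = next(w_iter, None)
        events.append(
            PhonemeEvent(
                onset=a, phoneme=ph, word_initial=initial, word=word,
                token_index=token,
            )
        )
    duration = float(xmax.group(1))
    return PhonemeTimeline(events=events, duration=duration)


# ---------------------------------------------------------------------------
# lexicon TSV: word <tab> space-separated phonemes <tab> count


def write_lexicon(path: Path | str, lexicon: ToyLexicon) -> None:
    lines = [f"{e.word}\t{' '.join(e.phonemes)}\t{e.count}" for e in lexicon.entries]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_lexicon(path: Path | str) -> ToyLexicon:
    entries = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DataError(f"{path}:{ln}: expected 3 tab-separated fields")
        entries.append(
            LexiconEntry(
                word=parts[0], phonemes=tuple(parts[1].split()), count=int(parts[2])
            )
        )
    return ToyLexicon(entries=entries)


# ---------------------------------------------------------------------------
# binary array container + JSON sidecar


def save_array(path: Path | str, data: np.ndarray, **meta) -> None:
    """Write a 2-D array as flat '<f8' binary with a .json sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(np.asarray(data, dtype="<f8"))
    atomic_write_bytes(path, data.tobytes())
    sidecar = {"shape": list(data.shape), "dtype": "<f8", **meta}
    atomic_write_text(path.with_suffix(path.suffix + ".json"),
                      json.dumps(sidecar, indent=1, sort_keys=True))


def load_array(path: Path | str) -> tuple[np.ndarray, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.frombuffer(Path(path).read_bytes(), dtype=sidecar["dtype"])
    data = data.reshape(sidecar["shape"]).copy()
    meta = {k: v for k, v in sidecar.items() if k not in ("shape", "dtype")}
    return data, meta


def save_impulse_series(path: Path | str, series: ImpulseSeries) -> None:
    payload = {
        "fs": series.fs,
        "n_samples": series.n_samples,
        "name": series.name,
        "events": [[int(i), float(v)] for i, v in zip(series.indices, series.values)],
    }
    atomic_write_text(path, json.dumps(payload, indent=1))


def load_impulse_series(path: Path | str) -> ImpulseSeries:
    payload = json.loads(Path(path).read_text())
    idx = [e[0] for e in payload["events"]]
    val = [e[1] for e in payload["events"]]
    return ImpulseSeries(
        fs=payload["fs"], n_samples=payload["n_samples"], name=payload["name"],
        indices=np.asarray(idx, dtype=int), values=np.asarray(val),
    )


def save_spectrogram(path: Path | str, spec: Spectrogram) -> None:
    save_array(
        path, spec.values, fs=spec.fs,
        band_centers=spec.band_centers.tolist(),
        transform="log1p" if spec.compressed else "linear",
    )


def load_spectrogram(path: Path | str) -> Spectrogram:
    data, meta = load_array(path)
    return Spectrogram(
        values=data, band_centers=np.asarray(meta["band_centers"]),
        fs=meta["fs"], compressed=meta["transform"] == "log1p",
    )
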