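"""End-to-end recipes: simulate -> predictors -> fit -> compare -> stats.

Every stage writes its artifacts plus a manifest (inputs, outputs, config
hash, seed — all content-hashed, no timestamps, so reruns with the same
seeds produce bit-identical manifests).  A downstream stage verifies the
hashes of its inputs against the producing stage's manifest and refuses to
run on tampered or missing artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from . import io as stio
from .basis import LagBasis
from .containers import ImpulseSeries
from .errors import ConfigError, DataError
from .inference import SensorAdjacency, cluster_test_one_sample
from .linguistics import cohort_predictors, segmentation_predictors
from .model import BoostingTRF, delta_z, make_cv_scheme
from .synth import (
    generate_lexicon_and_corpus,
    noise_sigma_for_snr,
    synthesize_eeg,
    timeline_from_corpus,
)

__all__ = ["PipelineConfig", "run_recipe", "resample_predictor", "RECIPES"]

RECIPES = ("simulate", "predictors", "fit", "compare", "stats", "all")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end pipeline.

    Rates and windows follow the standard recording contract: predictors on
    a 1 kHz grid, EEG at 100 Hz band-limited to 1-15 Hz, kernels on a
    -100..500 ms lag axis in a 50 ms Hamming basis, fivefold
    cross-validation, epochs capped at 61 s.
    """

    predictor_fs: float = 1000.0
    eeg_fs: float = 100.0
    lag_tmin: float = -0.100
    lag_tmax: float = 0.500
    basis_window: float = 0.050
    n_folds: int = 5
    filter_band: tuple[float, float] = (1.0, 15.0)
    epoch_cap: float = 61.0
    seed: int = 0
    out_dir: str = "speechtrf_out"
    # simulation: trial structure mirroring the experimental design
    n_subjects: int = 4
    n_trials: int = 15
    trial_duration: float = 60.0
    n_channels: int = 8
    snr_db: float = 10.0
    phoneme_rate: float = 8.0
    lexicon_words: int = 20
    corpus_len: int = 300
    # estimation
    step_frac: float = 0.005
    max_steps: int = 20000

    def __post_init__(self) -> None:
        if self.predictor_fs <= 0 or self.eeg_fs <= 0:
            raise ConfigError("sampling rates must be positive")
        if self.lag_tmin >= self.lag_tmax:
            raise ConfigError("lag window start must precede its end")
        if self.n_folds < 2:
            raise ConfigError("need at least 2 folds")
        self.filter_band = tuple(self.filter_band)  # type: ignore[assignment]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_band"] = list(self.filter_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Path | str) -> None:
        stio.atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as e:
            raise ConfigError(f"config file not found: {path}") from e
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def basis(self) -> LagBasis:
        return LagBasis(
            fs=self.eeg_fs, tmin=self.lag_tmin, tmax=self.lag_tmax,
            window=self.basis_window,
        )


# ---------------------------------------------------------------------------
# shared resampler


def resample_predictor(
    series: np.ndarray | ImpulseSeries, fs_in: float, fs_out: float
) -> np.ndarray | ImpulseSeries:
    """Resample a predictor from the 1 kHz grid to the EEG rate.

    Dense series are anti-alias filtered and decimated
    (``scipy.signal.resample_poly``); impulse series are re-binned under the
    half-open rule with impulse values conserved.  The decimation factor
    must be an integer.
    """
    if isinstance(series, ImpulseSeries):
        return series.resample(fs_out)
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigError(f"non-integer decimation factor {factor}")
    x = np.asarray(series, dtype=float)
    return sps.resample_poly(x, 1, int(round(factor)), axis=-1)


# ---------------------------------------------------------------------------
# manifests


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    out: Path, stage: str, cfg: PipelineConfig,
    inputs: list[Path], outputs: list[Path],
) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    stio.atomic_write_text(
        out / f"{stage}_manifest.json", json.dumps(manifest, indent=1, sort_keys=True)
    )


def _require_upstream(out: Path, stage: str, producer: str) -> dict:
    path = out / f"{producer}_manifest.json"
    if not path.exists():
        raise DataError(
            f"stage {stage!r} needs artifacts from {producer!r}; "
            f"run `speechtrf {producer}` first"
        )
    manifest = json.loads(path.read_text())
    for name, digest in manifest["outputs"].items():
        target = out / name
        if not target.exists():
            raise DataError(f"artifact {name} (from {producer!r}) is missing")
        if _sha256(target) != digest:
            raise DataError(
                f"artifact {name} does not match the {producer!r} manifest; "
                f"it was modified — rerun `speechtrf {producer}`"
            )
    return manifest


# ---------------------------------------------------------------------------
# stages


def _subject_seeds(cfg: PipelineConfig) -> list[int]:
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_subjects)]


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    lexicon, corpus = generate_lexicon_and_corpus(
        n_words=cfg.lexicon_words, corpus_len=cfg.corpus_len, seed=cfg.seed
    )
    timeline = timeline_from_corpus(
        corpus, lexicon, phoneme_rate=cfg.phoneme_rate, seed=cfg.seed
    )
    outputs: list[Path] = []
    stio.write_lexicon(out / "lexicon.tsv", lexicon)
    stio.write_textgrid(out / "timeline.TextGrid", timeline)
    outputs += [out / "lexicon.tsv", out / "timeline.TextGrid"]

    # ground-truth responses: predictors at EEG rate, smooth random kernels
    basis = cfg.basis()
    word_onset, _ = segmentation_predictors(timeline, fs=cfg.predictor_fs)
    surprisal, _ = cohort_predictors(timeline, lexicon, fs=cfg.predictor_fs)
    duration = min(timeline.duration, cfg.n_trials * cfg.trial_duration)
    n_samples = int(duration * cfg.eeg_fs)
    trial_len = int(cfg.trial_duration * cfg.eeg_fs)
    n_trials = min(cfg.n_trials, n_samples // trial_len)
    if n_trials < cfg.n_folds:
        raise ConfigError(
            "corpus too short for the requested trial structure; increase "
            "corpus_len or reduce n_trials/trial_duration"
        )
    n_samples = n_trials * trial_len
    bounds = [(i * trial_len, (i + 1) * trial_len) for i in range(n_trials)]
    preds = {
        "word_onset": resample_predictor(word_onset, cfg.predictor_fs, cfg.eeg_fs)
        .to_dense()[None, :n_samples],
        "wordform_surprisal": resample_predictor(
            surprisal, cfg.predictor_fs, cfg.eeg_fs
        ).to_dense()[None, :n_samples],
    }
    rng = np.random.default_rng(cfg.seed)
    kernels = {}
    t = basis.lags
    for name in preds:
        peak = rng.uniform(0.05, 0.25)
        amp = rng.uniform(0.5, 1.5, size=cfg.n_channels) * rng.choice([-1, 1])
        shape = np.exp(-0.5 * ((t - peak) / 0.05) ** 2) * np.sin(
            2 * np.pi * (t - peak) / 0.3
        )
        kernels[name] = shape[None, :, None] * amp[None, None, :]
    sig_probe = synthesize_eeg(
        preds, kernels, basis.lag_samples, cfg.eeg_fs, 0.0, bounds, seed=0,
        n_channels=cfg.n_channels,
    ).signal
    sigma = noise_sigma_for_snr(sig_probe, cfg.snr_db)
    for s, seed in enumerate(_subject_seeds(cfg)):
        eeg = synthesize_eeg(
            preds, kernels, basis.lag_samples, cfg.eeg_fs, sigma, bounds,
            seed=seed, n_channels=cfg.n_channels,
        )
        path = out / f"eeg_s{s:02d}.bin"
        stio.save_array(
            path, eeg.data, fs=cfg.eeg_fs, channel_names=list(eeg.channel_names),
            trial_bounds=[list(b) for b in bounds], subject_seed=seed,
        )
        outputs += [path, path.with_suffix(".bin.json")]
    for name, k in kernels.items():
        path = out / f"ground_truth_{name}.bin"
        stio.save_array(path, k[0], lags_s=basis.lags.tolist())
        outputs += [path, path.with_suffix(".bin.json")]
    return outputs


def _stage_predictors(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require_upstream(out, "predictors", "simulate")
    lexicon = stio.read_lexicon(out / "lexicon.tsv")
    timeline = stio.read_textgrid(out / "timeline.TextGrid")
    word_onset, phoneme_onset = segmentation_predictors(timeline, fs=cfg.predictor_fs)
    wf_surp, wf_ent = cohort_predictors(timeline, lexicon, fs=cfg.predictor_fs)
    outputs = []
    for series in (word_onset, phoneme_onset, wf_surp, wf_ent):
        low = resample_predictor(series, cfg.predictor_fs, cfg.eeg_fs)
        path = out / f"pred_{series.name}.json"
        stio.save_impulse_series(path, low)
        outputs.append(path)
    return outputs


def _load_subject(cfg: PipelineConfig, out: Path, s: int):
    data, meta = stio.load_array(out / f"eeg_s{s:02d}.bin")
    bounds = [tuple(b) for b in meta["trial_bounds"]]
    return data, bounds, meta


def _predictor_matrix(out: Path, names: list[str], n_samples: int) -> dict:
    preds = {}
    for name in names:
        series = stio.load_impulse_series(out / f"pred_{name}.json")
        preds[name] = series.to_dense()[None, :n_samples]
    return preds


FULL_MODEL = ["word_onset", "wordform_surprisal"]
REDUCED_MODEL = ["word_onset"]


def _stage_fit(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require_upstream(out, "fit", "simulate")
    _require_upstream(out, "fit", "predictors")
    basis = cfg.basis()
    rows = []
    for s in range(cfg.n_subjects):
        data, bounds, _ = _load_subject(cfg, out, s)
        scheme = make_cv_scheme(len(bounds), seed=cfg.seed + s, n_folds=cfg.n_folds)
        for label, names in (("full", FULL_MODEL), ("reduced", REDUCED_MODEL)):
            preds = _predictor_matrix(out, names, data.shape[1])
            res = BoostingTRF(
                data, preds, fs=cfg.eeg_fs, trial_bounds=bounds, basis=basis,
                scheme=scheme, step_frac=cfg.step_frac, max_steps=cfg.max_steps,
            ).fit()
            for ch, (r, z) in enumerate(zip(res.accuracy.r, res.accuracy.z)):
                rows.append((s, label, ch, r, z))
    lines = ["subject\tmodel\tchannel\tr\tz"] + [
        f"{s}\t{m}\t{ch}\t{r:.10g}\t{z:.10g}" for s, m, ch, r, z in rows
    ]
    path = out / "accuracy.tsv"
    stio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


def _read_accuracy(out: Path) -> dict:
    table: dict = {}
    lines = (out / "accuracy.tsv").read_text().splitlines()[1:]
    for line in lines:
        s, m, ch, r, z = line.split("\t")
        table.setdefault(m, {}).setdefault(int(s), {})[int(ch)] = float(z)
    return table


def _stage_compare(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require_upstream(out, "compare", "fit")
    table = _read_accuracy(out)
    lines = ["subject\tchannel\tdelta_z"]
    for s in sorted(table["full"]):
        for ch in sorted(table["full"][s]):
            dz = table["full"][s][ch] - table["reduced"][s][ch]
            lines.append(f"{s}\t{ch}\t{dz:.10g}")
    path = out / "delta_z.tsv"
    stio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


def _stage_stats(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require_upstream(out, "stats", "compare")
    rows: dict[int, dict[int, float]] = {}
    for line in (out / "delta_z.tsv").read_text().splitlines()[1:]:
        s, ch, dz = line.split("\t")
        rows.setdefault(int(s), {})[int(ch)] = float(dz)
    subjects = sorted(rows)
    chans = sorted(rows[subjects[0]])
    x = np.array([[rows[s][c] for c in chans] for s in subjects])
    adjacency = SensorAdjacency.chain(len(chans), prefix="ch")
    result = cluster_test_one_sample(
        x, adjacency, tail="greater", n_perm=10000, seed=cfg.seed
    )
    lines = ["members\tmass\tt_max\tp"]
    for c in result.clusters:
        lines.append(
            f"{','.join(c.member_names)}\t{c.mass:.10g}\t{c.t_max:.10g}\t{c.p:.10g}"
        )
    path = out / "clusters.tsv"
    stio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


_STAGES = {
    "simulate": (_stage_simulate, []),
    "predictors": (_stage_predictors, ["simulate"]),
    "fit": (_stage_fit, ["simulate", "predictors"]),
    "compare": (_stage_compare, ["fit"]),
    "stats": (_stage_stats, ["compare"]),
}


def run_recipe(cfg: PipelineConfig, recipe: str) -> list[Path]:
    """Run one pipeline stage (or ``all``); returns the written artifacts."""
    if recipe not in RECIPES:
        raise ConfigError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "predictors", "fit", "compare", "stats"] if recipe == "all" \
        else [recipe]
    written: list[Path] = []
    for stage in stages:
        fn, producers = _STAGES[stage]
        outputs = fn(cfg, out)
        inputs = []
        for producer in producers:
            manifest = _require_upstream(out, stage, producer)
            inputs += [out / name for name in manifest["outputs"]]
        _write_manifest(out, stage, cfg, inputs, outputs)
        written += outputs
    return written
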