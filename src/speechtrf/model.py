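"""Multivariate TRF estimation: model and results objects.

:class:`BoostingTRF` holds the data (multichannel response, named predictor
series, trial structure) and the estimation settings (lag basis, fivefold
cross-validation scheme, boosting step size).  ``fit()`` runs the full
nested cross-validation — five test folds, and for each test fold four
train/validation rotations — and returns a :class:`TRFResults` with:

* per-predictor, per-channel kernels (the average over all 20 fitted
  models), in original response/predictor units;
* cross-validated prediction accuracy per channel: Pearson r between the
  concatenated held-out predictions and the measured response, and its
  Fisher z transform.  Because predictions never use their own test fold,
  the expected accuracy for an uninformative predictor set is z = 0.

The unique contribution of a predictor set is measured by
:func:`delta_z`: the drop in z when the set is removed from the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import LagBasis
from .boosting import BoostResult, boost_channel
from .containers import ImpulseSeries
from .errors import ConfigError, DataError, FitError

__all__ = [
    "CVScheme",
    "make_cv_scheme",
    "fisher_z",
    "delta_z",
    "combine_visual_trf",
    "BoostingTRF",
    "SingleTRFFit",
    "PredictionAccuracy",
    "TRFResults",
]


# ---------------------------------------------------------------------------
# cross-validation scheme


@dataclass(frozen=True)
class CVScheme:
    """Assignment of trials to test folds with train/validation rotations.

    For each test fold, every one of the remaining folds serves as the
    validation set once while the others train — yielding
    ``n_folds * (n_folds - 1)`` fitted models in total, none of which ever
    sees its test fold.
    """

    n_trials: int
    folds: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = [t for fold in self.folds for t in fold]
        if sorted(flat) != list(range(self.n_trials)):
            raise ConfigError("folds must partition the trials exactly")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ConfigError("fold sizes must differ by at most 1")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def rotations(self, test_fold: int) -> list[tuple[list[int], list[int]]]:
        """(train trials, validation trials) pairs for one test fold."""
        others = [i for i in range(self.n_folds) if i != test_fold]
        out = []
        for val in others:
            train = [t for i in others if i != val for t in self.folds[i]]
            out.append((sorted(train), sorted(self.folds[val])))
        return out


def make_cv_scheme(
    n_trials: int, seed: int | np.random.Generator = 0, n_folds: int = 5
) -> CVScheme:
    """Randomly assign trials to ``n_folds`` test folds of near-equal size."""
    if n_trials < n_folds:
        raise ConfigError(f"need at least {n_folds} trials, got {n_trials}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    folds = tuple(
        tuple(sorted(int(t) for t in perm[i::n_folds])) for i in range(n_folds)
    )
    return CVScheme(n_trials=n_trials, folds=folds)


# ---------------------------------------------------------------------------
# accuracy


def fisher_z(r: np.ndarray | float, cap: float = 15.0) -> np.ndarray | float:
    """Fisher z transform ``arctanh(r)`` of a correlation coefficient.

    ``|r| = 1`` maps to ``+/- cap`` with a warning; ``|r| > 1`` is a domain
    error.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise DataError("correlation coefficients must lie in [-1, 1]")
    at_limit = np.abs(r_arr) == 1
    if np.any(at_limit):
        warnings.warn(f"|r| = 1 capped at z = +/-{cap}", stacklevel=2)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r_arr)
    z = np.where(at_limit, np.sign(r_arr) * cap, z)
    return float(z) if np.isscalar(r) else z


@dataclass
class PredictionAccuracy:
    """Per-channel cross-validated prediction accuracy."""

    r: np.ndarray
    z: np.ndarray
    channel_names: tuple[str, ...]
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": self.channel_names, "r": self.r, "z": self.z}
        )


def delta_z(full: PredictionAccuracy, reduced: PredictionAccuracy) -> np.ndarray:
    """Unique predictive power: per-channel z(full) - z(reduced)."""
    if full.channel_names != reduced.channel_names:
        raise DataError("accuracy objects cover different channels")
    return full.z - reduced.z


def combine_visual_trf(
    onset_trf: np.ndarray,
    offset_trf: np.ndarray,
    lag_samples: np.ndarray,
    fs: float,
    stimulus_duration: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine onset and offset TRFs into one effective response function.

    The offset kernel is shifted by the stimulus duration and summed with
    the onset kernel where the lag axes overlap; for the standard
    -100..500 ms axis and a 500 ms stimulus the result spans -100..1000 ms
    relative to stimulus onset.  Returns ``(combined, lag_samples_out)``.
    """
    onset_trf = np.asarray(onset_trf, dtype=float)
    offset_trf = np.asarray(offset_trf, dtype=float)
    lag_samples = np.asarray(lag_samples)
    if onset_trf.shape != offset_trf.shape:
        raise DataError("onset and offset TRFs must share a shape")
    if onset_trf.shape[-1] != lag_samples.size:
        raise DataError("TRF lag axis does not match the lag sample grid")
    shift = int(round(stimulus_duration * fs))
    n = lag_samples.size
    out_lags = np.arange(lag_samples[0], lag_samples[-1] + shift + 1)
    combined = np.zeros(onset_trf.shape[:-1] + (out_lags.size,))
    combined[..., :n] += onset_trf
    combined[..., shift : shift + n] += offset_trf
    return combined, out_lags


# ---------------------------------------------------------------------------
# model


def _as_dense(name: str, x, fs: float, n_samples: int | None) -> np.ndarray:
    if isinstance(x, ImpulseSeries):
        if abs(x.fs - fs) > 1e-9:
            raise DataError(
                f"predictor {name!r} is on a {x.fs} Hz grid, expected {fs} Hz"
            )
        dense = x.to_dense()[None, :]
    else:
        dense = np.atleast_2d(np.asarray(x, dtype=float))
    if n_samples is not None and dense.shape[1] != n_samples:
        raise DataError(
            f"predictor {name!r} has {dense.shape[1]} samples, expected {n_samples}"
        )
    return dense


class BoostingTRF:
    """Boosting mTRF model of a multichannel response.

    Parameters
    ----------
    response
        ``(n_channels, n_samples)`` response (e.g., EEG at 100 Hz).
    predictors
        Mapping from predictor name to a dense ``(n_dims, n_samples)`` array
        or an :class:`ImpulseSeries` on the response grid.  All dimensions
        of one named predictor freeze as a unit during boosting (set
        ``freeze="dimension"`` to freeze per dimension instead).
    fs
        Sampling rate of the response grid (Hz).
    trial_bounds
        ``(start, stop)`` sample ranges of the trials; kernels never
        convolve across trial boundaries.
    basis
        :class:`LagBasis`; defaults to 50 ms Hamming windows centred on
        lags -100..500 ms at ``fs``.
    scheme
        :class:`CVScheme`; defaults to a seeded fivefold scheme.
    step_frac
        Coefficient increment as a fraction of the training response SD
        (predictor dimensions are rescaled to unit mean absolute value
        internally; kernels are reported in original units).
    """

    def __init__(
        self,
        response: np.ndarray,
        predictors: dict[str, np.ndarray | ImpulseSeries],
        fs: float = 100.0,
        trial_bounds: list[tuple[int, int]] | None = None,
        basis: LagBasis | None = None,
        scheme: CVScheme | None = None,
        step_frac: float = 0.005,
        max_steps: int = 20000,
        freeze: str = "predictor",
        channel_names: list[str] | None = None,
        seed: int = 0,
    ) -> None:
        self.response = np.atleast_2d(np.asarray(response, dtype=float))
        self.fs = float(fs)
        self.n_channels, self.n_samples = self.response.shape
        if trial_bounds is None:
            trial_bounds = [(0, self.n_samples)]
        self.trial_bounds = list(trial_bounds)
        if not predictors:
            raise ConfigError("at least one predictor is required")
        if freeze not in ("predictor", "dimension"):
            raise ConfigError("freeze must be 'predictor' or 'dimension'")
        self.predictors = {
            name: _as_dense(name, x, self.fs, self.n_samples)
            for name, x in predictors.items()
        }
        for name, x in self.predictors.items():
            for d in range(x.shape[0]):
                if np.all(x[d] == x[d, 0]):
                    raise FitError(
                        f"predictor {name!r} dimension {d} has zero variance"
                    )
        for ch in range(self.n_channels):
            if np.all(self.response[ch] == self.response[ch, 0]):
                raise FitError(f"response channel {ch} has zero variance")
        self.basis = basis if basis is not None else LagBasis(fs=self.fs)
        self.scheme = scheme  # built lazily by fit() when not supplied
        self._seed = seed
        if scheme is not None and scheme.n_trials != len(self.trial_bounds):
            raise ConfigError(
                f"CV scheme covers {scheme.n_trials} trials but the data "
                f"has {len(self.trial_bounds)}"
            )
        self.step_frac = float(step_frac)
        self.max_steps = int(max_steps)
        self.freeze = freeze
        self.channel_names = tuple(
            channel_names
            if channel_names is not None
            else (f"ch{i:02d}" for i in range(self.n_channels))
        )

        # column layout: for predictor p with n_dims dims, n_dims * n_coefs
        # columns; metadata maps columns back to (name, dim, coef index)
        self._col_pred: list[str] = []
        self._col_dim: list[int] = []
        blocks = []
        group_ids = []
        gid = 0
        for name, x in self.predictors.items():
            blocks.append(self.basis.design_matrix(x, self.trial_bounds))
            for d in range(x.shape[0]):
                self._col_pred += [name] * self.basis.n_coefs
                self._col_dim += [d] * self.basis.n_coefs
                group_ids += [gid if freeze == "dimension" else -1] * self.basis.n_coefs
                gid += 1
        if freeze == "predictor":
            names = list(self.predictors)
            group_ids = [names.index(p) for p in self._col_pred]
        self._design = np.vstack(blocks)
        self._group_ids = np.asarray(group_ids)
        self._scales = self._predictor_scales()

    # ------------------------------------------------------------------
    def _predictor_scales(self) -> np.ndarray:
        """Per-column scale: mean absolute value of the predictor dimension."""
        scales = np.empty(self._design.shape[0])
        i = 0
        for name, x in self.predictors.items():
            for d in range(x.shape[0]):
                scales[i : i + self.basis.n_coefs] = np.mean(np.abs(x[d]))
                i += self.basis.n_coefs
        return scales

    def _samples(self, trials: list[int]) -> np.ndarray:
        return np.concatenate(
            [np.arange(*self.trial_bounds[t]) for t in sorted(trials)]
        )

    # ------------------------------------------------------------------
    def fit_single(
        self, train_trials: list[int], val_trials: list[int]
    ) -> "SingleTRFFit":
        """One boosting fit on an explicit train/validation split."""
        if set(train_trials) & set(val_trials):
            raise ConfigError("train and validation trials overlap")
        tr = self._samples(train_trials)
        va = self._samples(val_trials)
        c_tr = np.ascontiguousarray(self._design[:, tr] / self._scales[:, None])
        c_va = np.ascontiguousarray(self._design[:, va] / self._scales[:, None])
        coefs = np.empty((self._design.shape[0], self.n_channels))
        results: list[BoostResult] = []
        for ch in range(self.n_channels):
            y_tr = self.response[ch, tr]
            y_va = self.response[ch, va]
            mu = y_tr.mean()
            delta = self.step_frac * float(y_tr.std())
            res = boost_channel(
                y_tr - mu,
                y_va - y_va.mean(),
                c_tr,
                c_va,
                self._group_ids,
                delta=delta,
                max_steps=self.max_steps,
            )
            coefs[:, ch] = res.coefs / self._scales  # back to original units
            results.append(res)
        return SingleTRFFit(
            model=self,
            coefs=coefs,
            train_trials=sorted(train_trials),
            val_trials=sorted(val_trials),
            channel_results=results,
        )

    def fit(self) -> "TRFResults":
        """Full nested cross-validation fit."""
        if self.scheme is None:
            self.scheme = make_cv_scheme(len(self.trial_bounds), seed=self._seed)
        predicted = np.zeros_like(self.response)
        fits: list[SingleTRFFit] = []
        for fold in range(self.scheme.n_folds):
            fold_fits = [
                self.fit_single(train, val)
                for train, val in self.scheme.rotations(fold)
            ]
            fits.extend(fold_fits)
            avg = np.mean([f.coefs for f in fold_fits], axis=0)
            te = self._samples(list(self.scheme.folds[fold]))
            predicted[:, te] = avg.T @ self._design[:, te]
        # accuracy on the concatenated test predictions, mean-centred
        r = np.empty(self.n_channels)
        for ch in range(self.n_channels):
            y = self.response[ch] - self.response[ch].mean()
            p = predicted[ch] - predicted[ch].mean()
            denom = np.sqrt((y**2).sum() * (p**2).sum())
            r[ch] = (y * p).sum() / denom if denom > 0 else 0.0
        accuracy = PredictionAccuracy(
            r=r, z=fisher_z(r), channel_names=self.channel_names
        )
        mean_coefs = np.mean([f.coefs for f in fits], axis=0)
        return TRFResults(
            model=self,
            coefs=mean_coefs,
            accuracy=accuracy,
            predicted=predicted,
            fits=fits,
        )


# ---------------------------------------------------------------------------
# results


class _KernelView:
    """Shared kernel accessors for single fits and averaged results."""

    model: BoostingTRF
    coefs: np.ndarray  # (n_cols, n_channels), original units

    def coef_block(self, name: str) -> np.ndarray:
        """Basis coefficients of one predictor: (n_dims, n_coefs, n_ch)."""
        if name not in self.model.predictors:
            raise DataError(f"unknown predictor {name!r}")
        mask = np.asarray([p == name for p in self.model._col_pred])
        n_dims = self.model.predictors[name].shape[0]
        block = self.coefs[mask]
        return block.reshape(n_dims, self.model.basis.n_coefs, -1)

    def kernel(self, name: str) -> np.ndarray:
        """Expanded lag-sample kernel of one predictor: (n_dims, n_lags, n_ch)."""
        block = self.coef_block(name)  # (n_dims, n_coefs, n_ch)
        return np.moveaxis(
            self.model.basis.expand(np.moveaxis(block, 1, -1)), -1, 1
        )

    @property
    def lags(self) -> np.ndarray:
        return self.model.basis.lags


@dataclass
class SingleTRFFit(_KernelView):
    """One boosting fit (one train/validation rotation), all channels."""

    model: BoostingTRF
    coefs: np.ndarray
    train_trials: list[int]
    val_trials: list[int]
    channel_results: list[BoostResult] = field(repr=False, default_factory=list)

    def predict(self, trials: list[int] | None = None) -> np.ndarray:
        idx = (
            self.model._samples(trials)
            if trials is not None
            else np.arange(self.model.n_samples)
        )
        return self.coefs.T @ self.model._design[:, idx]


@dataclass
class TRFResults(_KernelView):
    """Nested-CV boosting results: averaged kernels and prediction accuracy."""

    model: BoostingTRF
    coefs: np.ndarray
    accuracy: PredictionAccuracy
    predicted: np.ndarray = field(repr=False)
    fits: list[SingleTRFFit] = field(repr=False, default_factory=list)

    @property
    def kernels(self) -> dict[str, np.ndarray]:
        return {name: self.kernel(name) for name in self.model.predictors}

    def summary(self) -> str:
        """Text summary: per-channel accuracy and per-predictor kernel scale."""
        acc = self.accuracy.to_frame()
        lines = [
            "Boosting mTRF results",
            "=" * 60,
            f"channels: {self.model.n_channels}   samples: {self.model.n_samples} "
            f"@ {self.model.fs:g} Hz   trials: {len(self.model.trial_bounds)}",
            f"folds: {self.model.scheme.n_folds}   models fitted: {len(self.fits)}",
            f"lag window: {self.lags[0]*1e3:.0f}..{self.lags[-1]*1e3:.0f} ms",
            "",
            "Prediction accuracy (cross-validated)",
            acc.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
            f"mean z: {self.accuracy.z.mean(): .4f}",
            "",
            "Kernel RMS by predictor",
        ]
        for name in self.model.predictors:
            k = self.kernel(name)
            lines.append(f"  {name}: {np.sqrt(np.mean(k**2)):.5g}")
        return "\n".join(lines)

    def plot_kernels(self, name: str, ax=None):
        """Plot one predictor's kernels (all dims x channels) over lag."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = self.kernel(name)
        for d in range(k.shape[0]):
            ax.plot(self.lags * 1e3, k[d], lw=0.8)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("kernel amplitude")
        ax.set_title(name)
        return ax
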