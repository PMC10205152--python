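"""Lag axis and Hamming-window coefficient basis for temporal response functions.

A temporal response function (TRF) is a linear kernel ``h`` mapping a stimulus
feature ``x`` to a response ``y`` across time lags::

    y(t) = sum_l h(l) * x(t - l) + noise

Kernels are parameterised in a basis of overlapping Hamming windows: one
coefficient per lag sample, each contributing a 50 ms Hamming bump centred on
its lag.  The basis smooths the estimate and is what the boosting estimator
operates on; expansion from coefficients to the lag-sample kernel is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["LagBasis", "lagged_convolve"]


@dataclass(frozen=True)
class LagBasis:
    """Hamming-window basis over a lag axis at a fixed sampling rate.

    Parameters
    ----------
    fs
        Sampling rate of the response (Hz).  Default 100 Hz.
    tmin, tmax
        Lag-window *centre* range in seconds, default -0.1 to 0.5 s
        (stimulus leading the response by up to 500 ms).
    window
        Hamming window length in seconds (default 50 ms).  Windows are
        truncated at the edges of the lag axis.
    """

    fs: float = 100.0
    tmin: float = -0.100
    tmax: float = 0.500
    window: float = 0.050
    lag_samples: np.ndarray = field(init=False, repr=False)
    expansion: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.tmin >= self.tmax:
            raise ConfigError("lag window start must precede its end")
        lo = int(round(self.tmin * self.fs))
        hi = int(round(self.tmax * self.fs))
        lags = np.arange(lo, hi + 1)
        n = lags.size
        length = int(round(self.window * self.fs))
        if length % 2 == 0:
            length += 1  # symmetric bump centred on the lag sample
        half = length // 2
        win = np.hamming(length)
        expansion = np.zeros((n, n))
        for j in range(n):
            a = max(0, j - half)
            b = min(n, j + half + 1)
            expansion[a:b, j] = win[a - (j - half) : b - (j - half)]
        object.__setattr__(self, "lag_samples", lags)
        object.__setattr__(self, "expansion", expansion)

    @property
    def n_coefs(self) -> int:
        return self.lag_samples.size

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size

    @property
    def lags(self) -> np.ndarray:
        """Lag axis in seconds."""
        return self.lag_samples / self.fs

    def expand(self, coefs: np.ndarray) -> np.ndarray:
        """Expand basis coefficients (last axis) to a lag-sample kernel."""
        coefs = np.asarray(coefs)
        if coefs.shape[-1] != self.n_coefs:
            raise ConfigError(
                f"expected {self.n_coefs} coefficients, got {coefs.shape[-1]}"
            )
        return coefs @ self.expansion.T

    def design_matrix(
        self,
        x: np.ndarray,
        trial_bounds: list[tuple[int, int]] | None = None,
    ) -> np.ndarray:
        """Basis-convolved design matrix for one multi-dimensional predictor.

        ``x`` is ``(n_dims, n_samples)`` at the basis sampling rate.  Returns
        ``(n_dims * n_coefs, n_samples)`` where row ``d * n_coefs + j`` is the
        predictor dimension ``d`` convolved with basis window ``j``.
        Convolution is computed independently per trial: no sample leaks
        across a trial boundary, missing lags are zero-padded.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n_dims, n_samples = x.shape
        lagged = _lagged(x, self.lag_samples, trial_bounds, n_samples)
        # (n_dims, n_lags, T) -> (n_dims, n_coefs, T)
        out = np.einsum("lj,dlt->djt", self.expansion, lagged)
        return out.reshape(n_dims * self.n_coefs, n_samples)


def _bounds_or_full(
    trial_bounds: list[tuple[int, int]] | None, n_samples: int
) -> list[tuple[int, int]]:
    if trial_bounds is None:
        return [(0, n_samples)]
    for a, b in trial_bounds:
        if not (0 <= a < b <= n_samples):
            raise ConfigError(f"trial bounds ({a}, {b}) outside [0, {n_samples})")
    return list(trial_bounds)


def _lagged(
    x: np.ndarray,
    lag_samples: np.ndarray,
    trial_bounds: list[tuple[int, int]] | None,
    n_samples: int,
) -> np.ndarray:
    n_dims = x.shape[0]
    lagged = np.zeros((n_dims, lag_samples.size, n_samples))
    for a, b in _bounds_or_full(trial_bounds, n_samples):
        for i, lag in enumerate(lag_samples):
            # y[t] uses x[t - lag]; keep both indices inside [a, b)
            t0 = max(a, a + lag)
            t1 = min(b, b + lag)
            if t0 < t1:
                lagged[:, i, t0:t1] = x[:, t0 - lag : t1 - lag]
    return lagged


def lagged_convolve(
    x: np.ndarray,
    kernel: np.ndarray,
    lag_samples: np.ndarray,
    trial_bounds: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Convolve a predictor with lag-sample kernels, per trial.

    ``x``: ``(n_dims, n_samples)``; ``kernel``: ``(n_dims, n_lags)`` or
    ``(n_dims, n_lags, n_channels)``.  Returns ``(n_samples,)`` or
    ``(n_channels, n_samples)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] != x.shape[0] or kernel.shape[1] != len(lag_samples):
        raise ConfigError(
            f"kernel shape {kernel.shape} does not match predictor "
            f"({x.shape[0]} dims) and lag axis ({len(lag_samples)} lags)"
        )
    lagged = _lagged(x, np.asarray(lag_samples), trial_bounds, x.shape[1])
    if kernel.ndim == 2:
        return np.einsum("dl,dlt->t", kernel, lagged)
    return np.einsum("dlc,dlt->ct", kernel, lagged)
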