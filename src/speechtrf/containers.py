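"""Core data containers: sparse impulse predictors and spectrograms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["ImpulseSeries", "Spectrogram"]


@dataclass
class ImpulseSeries:
    """Sparse event predictor: impulses of variable size on a uniform grid.

    Events are ``(sample_index, value)`` pairs at rate ``fs``.  An event at
    time ``t`` maps to sample ``floor(t * fs)`` (half-open bins); events
    landing on the same sample sum their values.
    """

    fs: float
    n_samples: int
    name: str = ""
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.indices.shape != self.values.shape:
            raise DataError("indices and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"non-finite impulse value in series {self.name!r}")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.n_samples
        ):
            raise DataError(f"event index outside grid in series {self.name!r}")

    @classmethod
    def from_times(
        cls,
        times: np.ndarray,
        values: np.ndarray,
        fs: float,
        duration: float,
        name: str = "",
    ) -> "ImpulseSeries":
        """Bin events at continuous times onto the grid, summing collisions."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        n_samples = int(np.floor(duration * fs))
        idx = np.floor(times * fs).astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= n_samples):
            raise DataError("event time outside [0, duration)")
        uniq, inv = np.unique(idx, return_inverse=True)
        summed = np.zeros(uniq.size)
        np.add.at(summed, inv, values)
        return cls(fs=fs, n_samples=n_samples, name=name, indices=uniq, values=summed)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.n_samples)
        np.add.at(dense, self.indices, self.values)
        return dense

    def resample(self, target_fs: float) -> "ImpulseSeries":
        """Re-bin to a lower rate by integer decimation, preserving values.

        Each event moves to ``old_index // factor``; values on a common
        target sample are summed, so the total impulse mass is conserved.
        """
        factor = self.fs / target_fs
        if abs(factor - round(factor)) > 1e-9:
            raise ConfigError(
                f"decimation factor {factor} is not an integer "
                f"({self.fs} Hz -> {target_fs} Hz)"
            )
        factor = int(round(factor))
        n_out = self.n_samples // factor
        idx = self.indices // factor
        keep = idx < n_out
        uniq, inv = np.unique(idx[keep], return_inverse=True)
        summed = np.zeros(uniq.size)
        np.add.at(summed, inv, self.values[keep])
        return ImpulseSeries(
            fs=target_fs, n_samples=n_out, name=self.name, indices=uniq, values=summed
        )

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class Spectrogram:
    """Band x time array of nonnegative acoustic magnitude.

    ``compressed`` records whether the values are log(1 + x) transformed.
    """

    values: np.ndarray
    band_centers: np.ndarray
    fs: float
    compressed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 2:
            raise DataError("spectrogram must be 2-D (band x time)")
        if self.values.shape[0] != self.band_centers.size:
            raise DataError("one center frequency required per band")
        if np.any(np.diff(self.band_centers) <= 0):
            raise DataError("band centers must be strictly increasing")
        if np.any(self.values < 0):
            raise DataError("spectrogram values must be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def compress(self) -> "Spectrogram":
        """Apply log(1 + x) magnitude compression."""
        if self.compressed:
            return self
        return Spectrogram(np.log1p(self.values), self.band_centers, self.fs, True)

    def decompress(self) -> "Spectrogram":
        if not self.compressed:
            return self
        return Spectrogram(np.expm1(self.values), self.band_centers, self.fs, False)
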