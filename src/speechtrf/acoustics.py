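"""Acoustic predictors: gammatone spectrograms and acoustic-onset detection.

The acoustic predictors are derived from a fine 256-band gammatone
spectrogram of the speech waveform (4th-order IIR gammatone filters,
ERB-rate-spaced center frequencies between 20 Hz and 5 kHz).  Band envelopes
are half-wave rectified filter outputs, low-pass filtered and decimated to
1 kHz, then log(1 + x) compressed.  Two derived 8-band predictors follow:

* the *spectrogram* predictor: the fine bands summed into 8 logarithmically
  spaced frequency bands;
* the *onset spectrogram* predictor: a per-band auditory edge detector
  (delayed-inhibition rectifier) applied to the fine bands before the same
  8-band summation.  It responds to energy increments only: a constant input
  yields exactly zero, a downward step yields zero, an upward step yields a
  transient pulse.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import Spectrogram
from .errors import ConfigError, DataError

__all__ = [
    "erb_space",
    "gammatone_fine",
    "band_sum",
    "band_edges",
    "edge_detect",
]


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """``n`` center frequencies equally spaced on the ERB-rate scale."""
    # Glasberg & Moore ERB-rate: E(f) = 21.4 log10(1 + 0.00437 f)
    e_lo = 21.4 * np.log10(1 + 0.00437 * f_lo)
    e_hi = 21.4 * np.log10(1 + 0.00437 * f_hi)
    e = np.linspace(e_lo, e_hi, n)
    return (10 ** (e / 21.4) - 1) / 0.00437


def _gammatone_sos(fc: float, fs: float) -> np.ndarray:
    """4th-order gammatone filter as a stable cascade of 4 biquads.

    Classic ERB-filterbank construction: four second-order sections sharing
    the resonator poles ``exp(-B T) exp(+/- i 2 pi fc T)`` with the standard
    four zero placements; the cascade gain is normalised to 1 at ``fc``.
    Stable for any center frequency (poles strictly inside the unit circle),
    unlike a single flattened 8th-order transfer function.
    """
    T = 1.0 / fs
    erb = 24.7 * (4.37e-3 * fc + 1.0)
    B = 1.019 * 2 * np.pi * erb
    theta = 2 * np.pi * fc * T
    pole_r = np.exp(-B * T)
    b1 = -2 * np.cos(theta) * pole_r
    b2 = pole_r**2
    k1 = np.sqrt(3 + 2**1.5)
    k2 = np.sqrt(3 - 2**1.5)
    zeros = [
        -(2 * T * np.cos(theta) + 2 * k1 * T * np.sin(theta)) * pole_r / 2,
        -(2 * T * np.cos(theta) - 2 * k1 * T * np.sin(theta)) * pole_r / 2,
        -(2 * T * np.cos(theta) + 2 * k2 * T * np.sin(theta)) * pole_r / 2,
        -(2 * T * np.cos(theta) - 2 * k2 * T * np.sin(theta)) * pole_r / 2,
    ]
    sos = np.array([[T, a1, 0.0, 1.0, b1, b2] for a1 in zeros])
    # normalise gain to unity at the center frequency
    w, h = sps.sosfreqz(sos, worN=[theta], fs=2 * np.pi)
    sos[0, :3] /= np.abs(h[0])
    return sos


def gammatone_fine(
    wave: np.ndarray,
    rate: float,
    n_bands: int = 256,
    f_lo: float = 20.0,
    f_hi: float = 5000.0,
    out_fs: float = 1000.0,
    compress: bool = True,
) -> Spectrogram:
    """Fine gammatone spectrogram of a mono waveform.

    Each band is a 4th-order IIR gammatone filter; the band envelope is the
    half-wave rectified output low-passed at ``out_fs / 2 * 0.8`` and
    resampled to ``out_fs``.  With ``compress`` the values are log(1 + x)
    transformed.  The number of output frames is ``floor(duration * out_fs)``
    (the shared frame-count rule).
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise DataError("waveform must be mono (1-D)")
    if rate < 2 * f_hi:
        raise DataError(
            f"sampling rate {rate} Hz too low for a {f_hi} Hz upper band edge"
        )
    centers = erb_space(f_lo, f_hi, n_bands)
    n_out = int(np.floor(wave.size / rate * out_fs))
    # anti-alias filter for envelope decimation
    lp = sps.butter(4, 0.8 * (out_fs / 2), btype="low", fs=rate, output="sos")
    bands = np.empty((n_bands, n_out))
    t_idx = np.floor(np.arange(n_out) / out_fs * rate).astype(int)
    for i, fc in enumerate(centers):
        env = np.maximum(sps.sosfilt(_gammatone_sos(fc, rate), wave), 0.0)
        env = np.maximum(sps.sosfilt(lp, env), 0.0)
        bands[i] = env[t_idx]
    spec = Spectrogram(bands, centers, out_fs, compressed=False)
    return spec.compress() if compress else spec


def band_edges(f_lo: float, f_hi: float, n_out: int) -> np.ndarray:
    """Logarithmically spaced frequency edges partitioning [f_lo, f_hi]."""
    return np.geomspace(f_lo, f_hi, n_out + 1)


def band_sum(fine: Spectrogram, n_out: int = 8) -> Spectrogram:
    """Sum fine bands into ``n_out`` logarithmically spaced frequency bands.

    Every fine band is assigned to exactly one output band by its center
    frequency, so the partition conserves total (uncompressed) energy.
    """
    if n_out < 1 or n_out > fine.n_bands:
        raise ConfigError(
            f"cannot sum {fine.n_bands} bands into {n_out} output bands"
        )
    edges = band_edges(fine.band_centers[0], fine.band_centers[-1], n_out)
    # half-open bins; the top band closes the interval
    group = np.clip(np.searchsorted(edges, fine.band_centers, side="right") - 1,
                    0, n_out - 1)
    if len(set(group.tolist())) != n_out:
        raise ConfigError(
            f"log-spaced partition into {n_out} bands leaves empty groups"
        )
    values = np.zeros((n_out, fine.n_samples))
    centers = np.empty(n_out)
    for g in range(n_out):
        members = group == g
        values[g] = fine.values[members].sum(axis=0)
        centers[g] = np.sqrt(edges[g] * edges[g + 1])  # geometric band center
    return Spectrogram(values, centers, fine.fs, compressed=fine.compressed)


def edge_detect(
    fine: Spectrogram,
    delay_ms: float = 10.0,
    inhibition_strength: float = 1.0,
    smooth_ms: float = 10.0,
) -> Spectrogram:
    """Auditory edge detection: rectified delayed inhibition per band.

    Each band's onset response is ``o(t) = max(0, x(t) - c * m(t - d))``
    where ``m`` is a ``smooth_ms`` moving average of the band and ``d`` is
    ``delay_ms``.  With ``c = 1`` any constant region maps to exactly zero
    and only energy *increments* produce output.
    """
    x = fine.values
    fs = fine.fs
    win = max(1, int(round(smooth_ms * fs / 1000.0)))
    delay = max(1, int(round(delay_ms * fs / 1000.0)))
    # causal moving average m[t] = mean(x[max(0, t-win+1) .. t]); partial
    # windows at the start use the true sample count so constants stay exact
    cs = np.cumsum(x, axis=1)
    m = np.empty_like(x)
    m[:, :win] = cs[:, :win] / np.arange(1, win + 1)
    if x.shape[1] > win:
        m[:, win:] = (cs[:, win:] - cs[:, :-win]) / win
    # inhibition uses m[t - delay]
    inh = np.zeros_like(x)
    inh[:, delay:] = m[:, :-delay]
    inh[:, :delay] = m[:, :1]  # warm-up: inhibit with the initial level
    onset = np.maximum(x - inhibition_strength * inh, 0.0)
    # numerical floor: running-sum round-off must not register as an onset
    onset[onset <= 1e-9 * max(np.abs(x).max(), 1e-300)] = 0.0
    return Spectrogram(onset, fine.band_centers, fs, compressed=fine.compressed)
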