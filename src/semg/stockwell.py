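"""Discrete Stockwell transform (S-transform) over a configurable band.

The S-transform is an invertible time-frequency representation that slides
a Gaussian window whose width is inversely proportional to frequency along
the signal before Fourier analysis:

    S(tau, f) = integral h(t) w(tau - t, f) exp(-i 2 pi f t) dt,
    w(t, f)   = |f| / sqrt(2 pi) * exp(-t^2 f^2 / 2).

Equivalently, in the frequency domain each "voice" at frequency f is the
inverse transform of the signal spectrum shifted by f and multiplied by a
Gaussian, R(alpha, f) = H(alpha + f) exp(-2 pi^2 alpha^2 / f^2).  The
discrete implementation below works row by row on the DFT of the signal:

    S[j, n] = sum_m H[(m + n) mod N] exp(-2 pi^2 m^2 / n^2) exp(i 2 pi m j / N)

with H the (1/N)-normalized DFT, m wrapped to the symmetric range
[-N/2, N/2), and the zero-frequency row defined as the signal mean.  This
gives low frequencies fine spectral resolution and high frequencies fine
temporal resolution, which suits the 10-500 Hz surface-EMG band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STConfig",
    "TimeFrequencyMatrix",
    "stransform",
    "tfm_modulus",
    "save_tfm",
    "load_tfm",
    "export_modulus_csv",
]


@dataclass(frozen=True)
class STConfig:
    """Frequency band and sampling rate for the transform.

    ``fmin``/``fmax`` bound the computed frequency rows (inclusive);
    rows outside the band are simply not computed.  ``detrend`` removes
    the mean before transforming and ``zero_pad`` appends that many zero
    samples; both default off.
    """

    fmin: float = 0.0
    fmax: float = 500.0
    fs: float = 2000.0
    detrend: bool = False
    zero_pad: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fmin < self.fmax <= self.fs / 2.0):
            raise ValueError(
                f"need 0 <= fmin < fmax <= fs/2, got fmin={self.fmin}, "
                f"fmax={self.fmax}, fs/2={self.fs / 2.0}"
            )
        if self.zero_pad < 0:
            raise ValueError("zero_pad must be >= 0")


@dataclass
class TimeFrequencyMatrix:
    """Complex S-transform output with explicit axes.

    ``values[k, j]`` is the transform at frequency ``freqs[k]`` and time
    ``times[j]``; rows lie on the n/(N T) grid and columns on the j T grid,
    where N is the (padded) data length and T the sampling period.
    """

    values: np.ndarray   # complex, (n_freqs, n_times)
    freqs: np.ndarray    # Hz, ascending
    times: np.ndarray    # seconds
    N: int
    T: float

    def __post_init__(self) -> None:
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("values shape inconsistent with axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFM contains non-finite entries")


# Cache of the last few Gaussian window banks; keyed by (N, n_lo, n_hi).
_WINDOW_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _window_bank(N: int, n_lo: int, n_hi: int) -> np.ndarray:
    """Gaussian voice windows exp(-2 pi^2 m^2 / n^2) for n in [n_lo, n_hi].

    m runs over DFT indices wrapped to the symmetric range so the window is
    even about zero frequency shift.
    """
    key = (N, n_lo, n_hi)
    bank = _WINDOW_CACHE.get(key)
    if bank is None:
        m = np.arange(N)
        m = np.where(m <= N // 2, m, m - N).astype(float)
        n = np.arange(n_lo, n_hi + 1, dtype=float)[:, None]
        bank = np.exp(-2.0 * np.pi**2 * m[None, :] ** 2 / n**2)
        if len(_WINDOW_CACHE) > 4:
            _WINDOW_CACHE.clear()
        _WINDOW_CACHE[key] = bank
    return bank


def stransform(signal: np.ndarray, config: STConfig) -> TimeFrequencyMatrix:
    """S-transform of a real signal over the configured frequency band.

    Returns one complex row per DFT frequency n/(N T) inside
    ``[fmin, fmax]``.  The zero-frequency row (present only when
    ``fmin = 0``) is the constant signal mean; every other row n is the
    inverse DFT of the cyclically shifted spectrum weighted by the
    frequency-scaled Gaussian.  Summing a row over time reproduces the
    signal's DFT coefficient at that frequency.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"signal too short ({x.size} samples); need >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if config.detrend:
        x = x - x.mean()
    if config.zero_pad:
        x = np.concatenate([x, np.zeros(config.zero_pad)])
    N = x.size
    T = 1.0 / config.fs
    df = 1.0 / (N * T)

    n_lo = int(np.ceil(config.fmin / df - 1e-9))
    n_hi = int(np.floor(config.fmax / df + 1e-9))
    n_hi = min(n_hi, N // 2)
    if n_hi < n_lo:
        raise ValueError("frequency band contains no DFT rows")

    X = np.fft.fft(x)
    rows = []
    start = n_lo
    if n_lo == 0:
        rows.append(np.full(N, x.mean(), dtype=complex))
        start = 1
    if n_hi >= start:
        bank = _window_bank(N, start, n_hi)
        n_idx = np.arange(start, n_hi + 1)
        shifted = X[(np.arange(N)[None, :] + n_idx[:, None]) % N]
        rows.append(np.fft.ifft(shifted * bank, axis=1))
    values = np.vstack(rows) if len(rows) > 1 else rows[0].reshape(-1, N)
    freqs = np.arange(n_lo, n_hi + 1) * df
    times = np.arange(N) * T
    return TimeFrequencyMatrix(values=values, freqs=freqs, times=times, N=N, T=T)


def tfm_modulus(tfm: TimeFrequencyMatrix) -> np.ndarray:
    """Elementwise modulus of the complex TFM (the matrix fed to SVD)."""
    return np.abs(tfm.values)


def save_tfm(tfm: TimeFrequencyMatrix, path) -> None:
    """Save a TFM to an ``.npz`` archive (values, freqs, times, N, T)."""
    np.savez(path, values=tfm.values, freqs=tfm.freqs, times=tfm.times,
             N=tfm.N, T=tfm.T)


def load_tfm(path) -> TimeFrequencyMatrix:
    with np.load(path) as data:
        return TimeFrequencyMatrix(
            values=data["values"], freqs=data["freqs"], times=data["times"],
            N=int(data["N"]), T=float(data["T"]),
        )


def export_modulus_csv(tfm: TimeFrequencyMatrix, path) -> None:
    """Write the modulus as CSV: first column frequency, then one column
    per time sample (header row of times in seconds)."""
    mod = tfm_modulus(tfm)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("freq_hz," + ",".join(f"{t:.9g}" for t in tfm.times) + "\n")
        for f, row in zip(tfm.freqs, mod):
            fh.write(f"{f:.9g}," + ",".join(f"{v:.9g}" for v in row) + "\n")
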