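"""Continuous wavelet transform and band-limited instantaneous phase.

Hemodynamic oscillations are analysed in four physiological frequency
intervals: I 0.6–2 Hz (cardiac), II 0.145–0.6 Hz (respiratory),
III 0.052–0.145 Hz (myogenic) and IV 0.021–0.052 Hz (neurogenic).  The
transform uses the complex Morlet wavelet

    ψ(u) = π^{-1/4} · exp(i 2π f0 u) · exp(−u²/2)

at scale s = f0/f per grid frequency, with central frequency f0 = 1 (the
admissibility correction is negligible at this f0 and is omitted).  A cone
of influence marks coefficients within one wavelet e-folding time (s·√2) of
either record edge; downstream averages exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .preprocess import butterworth_bandpass


@dataclass(frozen=True)
class FrequencyBand:
    id: str
    f_lo: float
    f_hi: float
    label: str

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")

    def contains(self, f: float) -> bool:
        """Half-open membership [f_lo, f_hi)."""
        return self.f_lo <= f < self.f_hi


#: The four canonical physiological intervals.
BANDS: dict[str, FrequencyBand] = {
    "I": FrequencyBand("I", 0.6, 2.0, "cardiac"),
    "II": FrequencyBand("II", 0.145, 0.6, "respiratory"),
    "III": FrequencyBand("III", 0.052, 0.145, "myogenic"),
    "IV": FrequencyBand("IV", 0.021, 0.052, "neurogenic"),
}


def band_assign(f: float) -> str | None:
    """Band id for a frequency, or None outside [0.021, 2) Hz.

    Boundaries follow the half-open convention: a shared edge belongs to the
    band whose lower bound it is.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    for band in BANDS.values():
        if band.contains(f):
            return band.id
    return None


def make_frequency_grid(f_min: float = 0.021, f_max: float = 2.0,
                        n_per_octave: int = 16) -> np.ndarray:
    """Log-spaced frequency grid inclusive of both endpoints."""
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n_per_octave < 1:
        raise ValueError("n_per_octave must be >= 1")
    n_oct = np.log2(f_max / f_min)
    n_pts = int(np.ceil(n_oct * n_per_octave)) + 1
    return f_min * 2.0 ** np.linspace(0.0, n_oct, n_pts)


@dataclass
class WaveletSpectrum:
    """Complex time–frequency coefficients on a log-spaced grid."""

    coefficients: np.ndarray  # (n_freq, n_time) complex
    frequency_grid: np.ndarray  # Hz, strictly increasing
    sampling_rate: float
    coi_mask: np.ndarray  # True where edge-affected
    f0: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequency_grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.coefficients.shape[0] != self.frequency_grid.size:
            raise ValueError("one coefficient row per grid frequency required")
        if self.coefficients.shape != self.coi_mask.shape:
            raise ValueError("coefficient/COI shape mismatch")

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[1]


@lru_cache(maxsize=8)
def _wavelet_kernels(grid_bytes: bytes, nfft: int, fs: float,
                     f0: float) -> np.ndarray:
    """Fourier-domain Morlet windows, one row per grid frequency.

    psi_hat(xi) = pi^{-1/4} sqrt(2 pi) exp(-(xi - 2 pi f0)^2 / 2); real, so
    conjugation is a no-op.  L2 scale normalisation contributes sqrt(s).
    Cached because one analysis reuses the same grid for many channels and
    surrogates.
    """
    grid = np.frombuffer(grid_bytes)
    scales = f0 / grid
    omega = 2 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    arg = scales[:, None] * omega[None, :] - 2 * np.pi * f0
    small = np.abs(arg) < 12.0  # exp(-72) is zero to double precision
    kernels = np.zeros_like(arg)
    kernels[small] = np.exp(-0.5 * arg[small] ** 2)
    kernels *= (np.pi ** -0.25) * np.sqrt(2 * np.pi * scales)[:, None]
    return kernels


def morlet_cwt(x: np.ndarray, fs: float, grid: np.ndarray,
               f0: float = 1.0) -> WaveletSpectrum:
    """Morlet continuous wavelet transform of a single channel.

    The signal mean is removed before the transform.  Computation is by FFT
    convolution with the analytic Morlet window at every grid frequency
    (L2 scale normalisation, so white-noise energy is flat across scale).
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid >= fs / 2):
        raise ValueError("grid frequencies must stay below the Nyquist rate")
    if np.any(grid <= 0):
        raise ValueError("grid frequencies must be positive")
    x = x - x.mean()
    n = x.size
    scales = f0 / grid  # seconds

    pad = int(np.ceil(5.0 * scales.max() * fs))
    nfft = next_fast_len(n + 2 * pad)
    xf = np.fft.fft(x, nfft)
    kernels = _wavelet_kernels(grid.tobytes(), nfft, fs, f0)
    coeff = np.fft.ifft(xf[None, :] * kernels, axis=1)[:, :n]

    t = np.arange(n) / fs
    efold = np.sqrt(2.0) * scales
    coi = (t[None, :] < efold[:, None]) | ((t[-1] - t)[None, :] < efold[:, None])
    return WaveletSpectrum(coeff, grid, fs, coi, f0)


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase of one channel in one band."""

    phase: np.ndarray  # rad, unwrapped
    sampling_rate: float
    band: str
    channel: int | None = None
    valid: np.ndarray | None = None  # False where edge-affected

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")

    @property
    def n_samples(self) -> int:
        return self.phase.size


def band_grid(band: FrequencyBand, n_per_octave: int = 16) -> np.ndarray:
    """Log grid spanning one band (upper edge excluded, half-open bands)."""
    g = make_frequency_grid(band.f_lo, band.f_hi, n_per_octave)
    return g[g < band.f_hi * (1 - 1e-12)]


def band_phase(x: np.ndarray, band: FrequencyBand, fs: float,
               method: str = "wavelet", n_per_octave: int = 16,
               filter_order: int = 3, f0: float = 1.0) -> PhaseSeries:
    """Instantaneous phase of one channel restricted to one band.

    method="wavelet"
        Phase of the amplitude-weighted circular mean of the wavelet
        coefficients across the band's grid frequencies (the coefficient sum:
        |W|-weighted mean of unit phasors W/|W|).
    method="analytic"
        Butterworth band-pass to [f_lo, f_hi] followed by the analytic-signal
        (Hilbert) phase; used for oscillator inference, which needs a single
        protophase per band.
    """
    x = np.asarray(x, dtype=float)
    min_len = 3.0 / band.f_lo * fs
    if x.size < min_len:
        raise ValueError(
            f"record shorter than 3 cycles of {band.f_lo} Hz "
            f"({x.size} < {min_len:.0f} samples)")
    if method == "wavelet":
        grid = band_grid(band, n_per_octave)
        spec = morlet_cwt(x, fs, grid, f0=f0)
        z = spec.coefficients.sum(axis=0)
        phase = np.unwrap(np.angle(z))
        valid = ~spec.coi_mask.any(axis=0)
    elif method == "analytic":
        xb = butterworth_bandpass(x, band.f_lo, band.f_hi, filter_order, fs)
        phase = np.unwrap(np.angle(hilbert(xb)))
        efold = np.sqrt(2.0) / band.f_lo
        t = np.arange(x.size) / fs
        valid = (t >= efold) & (t <= t[-1] - efold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PhaseSeries(phase, fs, band.id, valid=valid)
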