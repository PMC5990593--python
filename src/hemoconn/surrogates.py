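"""Amplitude-adjusted Fourier transform (AAFT) surrogates and thresholds.

AAFT surrogates preserve a signal's amplitude distribution exactly and its
power spectrum approximately while randomising Fourier phases, destroying
any phase relationship with other channels.  Connectivity statistics are
declared significant when they exceed the mean + 2·SD of the statistic over
a surrogate ensemble (one-sided, appropriate for non-negative statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def aaft_surrogate(x: np.ndarray,
                   seed: int | np.random.Generator | np.random.SeedSequence = 0
                   ) -> np.ndarray:
    """One AAFT surrogate of ``x``.

    Algorithm: (1) rank-remap ``x`` onto sorted Gaussian deviates;
    (2) randomise Fourier phases of the Gaussianised series, keeping the DC
    and Nyquist bins real; (3) rank-remap the result back onto the sorted
    original values.  ``sorted(surrogate) == sorted(x)`` holds exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant series has undefined ranks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    gauss = np.sort(rng.standard_normal(n))
    y = gauss[ranks]

    yf = np.fft.rfft(y)
    n_interior = yf.size - 1 - (1 if n % 2 == 0 else 0)
    phases = np.exp(2j * np.pi * rng.random(n_interior))
    yf[1:1 + n_interior] *= phases
    y_rand = np.fft.irfft(yf, n)

    return np.sort(x)[np.argsort(np.argsort(y_rand, kind="stable"), kind="stable")]


@dataclass
class SurrogateEnsemble:
    """Per-surrogate values of a statistic and their summary."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("need at least 2 surrogate values")

    @property
    def n_surrogates(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def significance_threshold(ensemble: SurrogateEnsemble | np.ndarray) -> float:
    """One-sided significance threshold: mean + 2·SD of the surrogate
    statistic.  A real statistic is significant iff it exceeds this."""
    if not isinstance(ensemble, SurrogateEnsemble):
        ensemble = SurrogateEnsemble(np.asarray(ensemble))
    return ensemble.mean + 2.0 * ensemble.sd
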