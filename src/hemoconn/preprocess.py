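"""Movement-artifact reduction and band-pass filtering.

Artifact handling follows the moving-standard-deviation / spline-subtraction
scheme (MARA): a centred moving SD marks samples whose local variability
exceeds a threshold, flagged segments are fitted with a cubic smoothing
spline that models the artifact's shape, the spline is subtracted, and the
record is re-levelled so the corrected segment and the subsequent data stay
continuous with the preceding clean samples.

Filtering is a zero-phase (forward–backward) Butterworth band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy.interpolate import make_smoothing_spline

from .recording import Recording

#: half-open sample ranges flagged as artifact
ArtifactSegments = list[tuple[int, int]]


@dataclass(frozen=True)
class MaraConfig:
    """Artifact-correction settings.

    window_length
        Moving-SD window in seconds.
    threshold
        Detection threshold as a multiple of the median of the moving-SD
        series (the robust scale of artifact-free variability).
    spline_parameter
        Smoothing parameter p in (0, 1]; p → 0 approaches a straight-line
        fit, p → 1 interpolation.  p = 0.01 follows the MARA literature.
    """

    window_length: float = 1.0  # s
    threshold: float = 5.0
    spline_parameter: float = 0.01
    merge_gap: float = 0.5  # s, nearby segments are merged

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.threshold <= 0:
            raise ValueError("window_length and threshold must be positive")
        if not 0 < self.spline_parameter <= 1:
            raise ValueError("spline_parameter must be in (0, 1]")


def moving_std(x: np.ndarray, window_length: float, fs: float) -> np.ndarray:
    """Centred moving sample standard deviation, edge windows truncated."""
    x = np.asarray(x, dtype=float)
    w = int(round(window_length * fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > x.size:
        raise ValueError("window longer than the signal")
    s = pd.Series(x).rolling(w, center=True, min_periods=1).std(ddof=1)
    return s.fillna(0.0).to_numpy()


def detect_artifact_segments(s: np.ndarray, threshold: float,
                             fs: float, merge_gap: float = 0.5
                             ) -> ArtifactSegments:
    """Contiguous runs where the moving SD exceeds ``threshold·median(s)``.

    Runs separated by less than ``merge_gap`` seconds are merged.  An
    all-zero SD series yields no segments.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("moving-SD series must be non-negative")
    med = float(np.median(s))
    mask = s > threshold * med
    if med == 0.0:
        mask = np.zeros_like(mask)
    segments: ArtifactSegments = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return segments
    gap = max(1, int(round(merge_gap * fs)))
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev >= gap:
            segments.append((int(start), int(prev) + 1))
            start = i
        prev = i
    segments.append((int(start), int(prev) + 1))
    return segments


def spline_artifact_correction(x: np.ndarray, segments: ArtifactSegments,
                               p: float = 0.01, fs: float = 10.0) -> np.ndarray:
    """Subtract a cubic smoothing spline from each artifact segment.

    Within a segment a smoothing spline with roughness weight p/(1−p)
    (p → 0: the spline follows the data, i.e. the artifact's full shape;
    p → 1: a straight-line fit) models the artifact; subtracting it leaves
    only the segment's fast residual.  The residual is re-levelled onto a
    linear bridge between the last clean sample before the segment and the
    first clean sample after it, so the corrected record is continuous at
    both segment boundaries — spikes are flattened and baseline-shift
    artifacts leave no discontinuity.  Samples outside the segments are
    never modified.  Segments shorter than 4 samples fall back to plain
    linear interpolation across the segment.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    for start, end in segments:
        if not 0 <= start < end <= x.size:
            raise ValueError(f"segment ({start}, {end}) outside the signal")
    for start, end in sorted(segments):
        seg = out[start:end].copy()
        n = end - start
        left = out[start - 1] if start > 0 else None
        right = out[end] if end < out.size else None
        if left is None:
            left = right if right is not None else float(np.median(seg))
        if right is None:
            right = left
        bridge = np.linspace(left, right, n + 2)[1:-1]
        if n < 4:
            out[start:end] = bridge
        else:
            t = np.arange(n, dtype=float)
            lam = p / (1.0 - p) if p < 1 else np.inf
            spline = make_smoothing_spline(t, seg, lam=lam)(t)
            out[start:end] = (seg - spline) + bridge
    return out


def butterworth_bandpass(x: np.ndarray, f_lo: float, f_hi: float,
                         order: int = 3, fs: float = 10.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward, length preserved)."""
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError("need 0 < f_lo < f_hi < fs/2")
    sos = sig.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class FilterConfig:
    """Default preprocessing band spans all four analysis intervals
    (0.021–2 Hz) with margin."""

    f_lo: float = 0.005
    f_hi: float = 2.0
    order: int = 3


def correct_channel(x: np.ndarray, fs: float,
                    mara: MaraConfig = MaraConfig()
                    ) -> tuple[np.ndarray, ArtifactSegments]:
    """Detect and spline-correct artifacts on one channel.

    Idempotent on artifact-free signals: with no flagged segments the input
    is returned bit-identically.
    """
    s = moving_std(x, mara.window_length, fs)
    segments = detect_artifact_segments(s, mara.threshold, fs, mara.merge_gap)
    if not segments:
        return np.asarray(x, dtype=float).copy(), segments
    return spline_artifact_correction(x, segments, mara.spline_parameter, fs), segments


def preprocess_recording(rec: Recording,
                         mara: MaraConfig = MaraConfig(),
                         filt: FilterConfig = FilterConfig()
                         ) -> tuple[Recording, pd.DataFrame]:
    """Artifact-correct and band-pass every channel of a recording.

    Returns the cleaned recording and a segments report with one row per
    corrected artifact (channel, start and end in seconds).
    """
    out = rec.copy()
    rows = []
    for i in range(rec.n_channels):
        corrected, segments = correct_channel(rec.samples[i], rec.sampling_rate, mara)
        out.samples[i] = butterworth_bandpass(
            corrected, filt.f_lo, filt.f_hi, filt.order, rec.sampling_rate)
        for start, end in segments:
            rows.append({"channel": rec.channel_names[i],
                         "start_s": start / rec.sampling_rate,
                         "end_s": end / rec.sampling_rate})
    report = pd.DataFrame(rows, columns=["channel", "start_s", "end_s"])
    return out, report
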