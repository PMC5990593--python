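"""Multi-channel hemodynamic recordings.

A :class:`Recording` holds a channels x samples matrix of hemoglobin-
concentration changes (Δ[HbO2]-like, arbitrary signal units) together with
the sampling rate, the channel → cortical-region map, and the study labels
(subject, group, condition).  Six cortical regions are recognised: left and
right prefrontal cortex (LPFC, RPFC), left and right motor cortex (LMC,
RMC), and left and right occipital lobe (LOL, ROL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical cortical regions, in fixed reporting order.
REGIONS: tuple[str, ...] = ("LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL")

DEFAULT_SAMPLING_RATE = 10.0


@dataclass
class Recording:
    """A single multi-channel recording from one subject in one condition.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal matrix; every channel has the same length by construction.
    sampling_rate : float
        Samples per second (10 Hz for the study montage).
    channel_regions : sequence of str
        Region label for each channel; labels must come from :data:`REGIONS`.
    subject_id, group, condition : str
        Study metadata labels.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    channel_regions: tuple[str, ...] = ()
    subject_id: str = "s01"
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_regions = tuple(self.channel_regions)
        if len(self.channel_regions) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_regions)} region labels for "
                f"{self.n_channels} channels"
            )
        bad = sorted(set(self.channel_regions) - set(REGIONS))
        if bad:
            raise ValueError(f"unknown region label(s): {bad}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"ch{i + 1:02d}" for i in range(self.n_channels))

    @property
    def regions(self) -> tuple[str, ...]:
        """Regions present, in canonical order."""
        present = set(self.channel_regions)
        return tuple(r for r in REGIONS if r in present)

    def region_channels(self, region: str) -> list[int]:
        """Channel indices belonging to ``region``."""
        return [i for i, r in enumerate(self.channel_regions) if r == region]

    def copy(self) -> "Recording":
        return replace(self, samples=self.samples.copy())


def default_channel_layout(n_per_region: int = 6,
                           regions: Sequence[str] = REGIONS) -> tuple[str, ...]:
    """Region label per channel for a homogeneous montage.

    The study montage has 36 channels, six per region; reduced layouts are
    used for fast synthetic analyses.
    """
    if n_per_region < 1:
        raise ValueError("n_per_region must be >= 1")
    return tuple(r for r in regions for _ in range(n_per_region))
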