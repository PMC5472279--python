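"""Shared container types used across the imaging, assay, structural and
flow-cytometry pipelines.

The containers are deliberately thin: plain dataclasses wrapping numpy
arrays or scalars, with validation in ``__post_init__`` so that every
pipeline stage can rely on the stated invariants (shared channel shapes,
positive pixel size, ordered population means, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Fixed vocabulary for DNA-content populations, in order of increasing
#: DNA-stain intensity: elongated spermatids, round spermatids (1C),
#: spermatogonia (2C) and primary spermatocytes (4C).
FLOW_POPULATIONS = ("ES", "RS", "2C", "4C")

#: Seminiferous-tubule stage groups used for Golgi-area summaries.
STAGE_GROUPS = ("II-III", "IV", "VI-VIII", "IX", "X-XII", "unknown")


@dataclass
class CalibratedImage:
    """Multi-channel 2D intensity image with a physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"dapi"``, ``"golgi"``) to a 2D
        non-negative float array. All channels must share one shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        self.channels = {name: np.asarray(ch, dtype=float) for name, ch in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not found; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class GolgiDensityRecord:
    """Per-Golgi record of the cell-culture density workflow.

    ``density`` is the ratio of the thresholded (stack) Golgi area to the
    hole-filled total Golgi area; a compact stacked Golgi scores near 1,
    a fragmented or perforated one scores lower.  ``golgi_to_nucleus_ratio``
    is emitted alongside as the per-cell size covariate.
    """

    cell_id: int
    golgi_stack_area_um2: float
    golgi_total_area_um2: float
    nucleus_area_um2: float
    density: float
    golgi_to_nucleus_ratio: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not (0.0 < self.density <= 1.0 + 1e-12):
                raise ValueError(f"density out of (0, 1]: {self.density}")
            if self.golgi_total_area_um2 < self.golgi_stack_area_um2 - 1e-12:
                raise ValueError("total Golgi area smaller than stack area")


@dataclass
class GolgiAreaRecord:
    """One segmented Golgi region in a tissue section."""

    region_id: int
    tubule_id: int
    stage_group: str
    area_um2: float
    above_threshold: bool

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("region area must be positive")
        if self.stage_group not in STAGE_GROUPS:
            raise ValueError(f"unknown stage group {self.stage_group!r}")


@dataclass
class StageSummary:
    """Per-stage aggregate of the fraction of large Golgi regions."""

    stage_group: str
    n_tubules: int
    n_regions: int
    percent_above: float          # mean of per-tubule percentages
    sem_percent_above: float
    per_tubule_percentages: list[float] = field(default_factory=list)
    pooled_percent_above: float = float("nan")  # regions pooled across tubules


@dataclass
class EventTable:
    """Per-event DNA-stain intensities with (optional) population labels."""

    intensity: np.ndarray
    label: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if self.intensity.ndim != 1 or self.label.shape != self.intensity.shape:
            raise ValueError("intensity and label must be matching 1D arrays")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        allowed = set(FLOW_POPULATIONS) | {"unassigned"}
        bad = set(self.label.tolist()) - allowed
        if bad:
            raise ValueError(f"labels outside fixed vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return self.intensity.size
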