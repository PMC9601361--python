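"""Shared containers for DCE-MRI radiomic analysis.

A study is a single representative slice imaged once before and eight
times after contrast injection.  Regions of interest are the lesion
(intratumoral), a ring dilated from its boundary (peritumoral) and the
breast parenchyma mask that bounds the ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_FRAMES = 9  # 1 pre-contrast + 8 post-contrast
REGION_TAGS = ("intratumoral", "peritumoral", "breast")


@dataclass
class DCEStudy:
    """One patient's 9-frame DCE time series plus geometry and labels.

    ``frames`` has shape ``(9, H, W)``; frame 0 is pre-contrast, frames
    1..8 are post-contrast.  Intensities are arbitrary units, finite and
    non-negative.  ``acquisition_index`` orders patients by time of
    treatment and drives the temporal cohort split.
    """

    patient_id: str
    frames: np.ndarray
    pixel_spacing_mm: float
    er_label: int
    pr_label: int
    acquisition_index: int
    # Optional synthetic ground truth (set by the cohort generator).
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != N_FRAMES:
            raise ValueError(
                f"frames must have shape (9, H, W); got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.er_label not in (0, 1) or self.pr_label not in (0, 1):
            raise ValueError("receptor labels must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RoiMask:
    """Binary region-of-interest raster on the representative slice."""

    pixels: np.ndarray
    region_tag: str
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.region_tag not in REGION_TAGS:
            raise ValueError(f"unknown region_tag {self.region_tag!r}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def __bool__(self) -> bool:  # non-empty
        return bool(self.pixels.any())


@dataclass
class RoiSet:
    """Intratumoral core, peritumoral ring and breast mask for one study."""

    intratumoral: RoiMask
    peritumoral: RoiMask
    breast: RoiMask

    def __post_init__(self) -> None:
        if np.any(self.intratumoral.pixels & self.peritumoral.pixels):
            raise ValueError("peritumoral ring overlaps the intratumoral core")
        if np.any(self.peritumoral.pixels & ~self.breast.pixels):
            raise ValueError("peritumoral ring extends outside the breast mask")


@dataclass
class SubtractionImage:
    """Post-contrast frame minus the pre-contrast frame.

    Negative values are retained; they are meaningful for thresholding.
    """

    pixels: np.ndarray
    source_timepoint: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not 1 <= self.source_timepoint <= 8:
            raise ValueError("source_timepoint must be in 1..8")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 for two empty masks)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
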