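"""Lesion and peritumoral-ring segmentation on subtraction images.

The intratumoral ROI comes from maximum between-class-variance (Otsu)
thresholding inside a user-supplied seed box on a post−pre subtraction
image; the peritumoral ROI is the ring obtained by dilating the lesion
boundary by a radial distance in millimetres, clipped to the breast
mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DCEStudy, RoiMask, RoiSet, SubtractionImage

__all__ = [
    "subtract_frames",
    "otsu_threshold",
    "segment_intratumoral",
    "dilate_peritumoral",
    "choose_subtraction_timepoint",
    "build_roi_set",
    "disk_structuring_element",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity


def subtract_frames(study: DCEStudy, timepoint: int) -> SubtractionImage:
    """Post-contrast frame minus pre-contrast frame (negatives retained)."""
    if not 1 <= timepoint <= 8:
        raise ValueError("timepoint must be in 1..8")
    return SubtractionImage(
        pixels=study.frames[timepoint] - study.frames[0],
        source_timepoint=timepoint,
    )


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance of a histogram.

    The histogram has ``n_bins`` equal-width bins over [min, max]; the
    returned threshold is the upper edge of the bin after which the cut
    is placed, so the two classes are ``x <= t`` and ``x > t``.  Ties in
    the between-class variance are broken toward the lower threshold.
    A constant input admits no separating threshold and raises.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0 or np.ptp(values) / n_bins == 0:
        raise ValueError("need at least 2 distinct values")
    counts, edges = np.histogram(values, bins=n_bins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]                       # weight of class <= cut k
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)[:-1]
    mu_total = (p * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (mu_total - cum_mean) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    # First cut within relative tolerance of the maximum: ties (e.g. a
    # plateau across an empty histogram gap) resolve to the lower threshold.
    best = sigma_b.max()
    tol = 1e-9 * max(abs(best), 1.0)
    k = int(np.argmax(sigma_b >= best - tol))
    return float(edges[k + 1])


def segment_intratumoral(sub: SubtractionImage, seed_box) -> RoiMask:
    """Otsu-based semi-automatic lesion segmentation inside a seed box.

    ``seed_box`` is ``(row0, row1, col0, col1)`` (half-open).  The
    threshold is computed from the pixels inside the box; the mask is
    the largest 8-connected supra-threshold component inside the box,
    holes filled.
    """
    r0, r1, c0, c1 = seed_box
    h, w = sub.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("seed_box outside image")
    window = sub.pixels[r0:r1, c0:c1]
    thr = otsu_threshold(window)
    supra = window > thr
    if not supra.any():
        raise ValueError("no supra-threshold pixels in seed box")
    labels, n_comp = ndimage.label(supra, structure=_EIGHT)
    sizes = ndimage.sum_labels(supra, labels, range(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = ndimage.binary_fill_holes(labels == largest)
    return RoiMask(mask, "intratumoral", pixel_spacing_mm=1.0)


def disk_structuring_element(radius_px: int) -> np.ndarray:
    """Disk of the given pixel radius (inclusive boundary)."""
    if radius_px < 1:
        raise ValueError("radius must be >= 1 px")
    y, x = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    return x * x + y * y <= radius_px * radius_px


def dilate_peritumoral(core: RoiMask, breast: RoiMask, radius_mm: float) -> RoiMask:
    """Peritumoral ring: dilate the core by ``radius_mm`` and clip.

    The structuring element is a disk of ``round(radius_mm / spacing)``
    pixels (Euclidean distance).  The ring excludes the core and never
    leaves the breast mask.
    """
    if not core:
        raise ValueError("core mask is empty")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if np.any(core.pixels & ~breast.pixels):
        raise ValueError("core must lie inside the breast mask")
    radius_px = int(round(radius_mm / core.pixel_spacing_mm))
    radius_px = max(radius_px, 1)
    dilated = ndimage.binary_dilation(
        core.pixels, structure=disk_structuring_element(radius_px)
    )
    ring = dilated & ~core.pixels & breast.pixels
    if not ring.any():
        raise ValueError("peritumoral ring is empty (core fills breast mask)")
    return RoiMask(ring, "peritumoral", core.pixel_spacing_mm)


def choose_subtraction_timepoint(study: DCEStudy, seed_box) -> int:
    """Post-contrast timepoint with maximum mean enhancement in the box."""
    r0, r1, c0, c1 = seed_box
    means = [
        float((study.frames[t, r0:r1, c0:c1] - study.frames[0, r0:r1, c0:c1]).mean())
        for t in range(1, 9)
    ]
    return int(np.argmax(means)) + 1


def build_roi_set(
    study: DCEStudy,
    seed_box,
    breast_mask: np.ndarray,
    radius_mm: float = 4.0,
    timepoint: int | None = None,
) -> RoiSet:
    """Segment one study: lesion core, 4 mm ring, breast bookkeeping."""
    if timepoint is None:
        timepoint = choose_subtraction_timepoint(study, seed_box)
    sub = subtract_frames(study, timepoint)
    core = segment_intratumoral(sub, seed_box)
    core = RoiMask(core.pixels, "intratumoral", study.pixel_spacing_mm)
    breast = RoiMask(
        np.asarray(breast_mask, dtype=bool) | core.pixels,
        "breast",
        study.pixel_spacing_mm,
    )
    ring = dilate_peritumoral(core, breast, radius_mm)
    return RoiSet(intratumoral=core, peritumoral=ring, breast=breast)
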