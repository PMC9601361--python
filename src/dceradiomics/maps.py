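"""Six semi-quantitative kinetic parametric maps from a DCE time series.

Per pixel, with SI_0 the pre-contrast intensity and SI_i (i = 1..8) the
post-contrast intensities:

* MSI       = max_i (SI_{i+1} − SI_i), i = 0..7      [intensity units]
* SI_slope  = 100 · (SI_8 − SI_mean) / SI_mean       [%], SI_mean = (SI_1+SI_2)/2
* E_initial = 100 · (SI_1 − SI_0) / SI_0             [%]
* ESER      = 100 · (SI_1 − SI_0) / (SI_2 − SI_0)    [%]
* E_peak    = 100 · (SI_peak − SI_0) / SI_0          [%]
* SEP       = 100 · (SI_2 − SI_0) / SI_0             [%]

SI_peak is taken at the peak timepoint of the region-mean
time–intensity curve (one timepoint per region; a per-pixel mode is
available).  Degenerate denominators yield 0 and set the flag raster:
flagged pixels stay in the ROI so region size is identical across maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DCEStudy, RoiMask

MAP_NAMES = ("msi", "si_slope", "e_initial", "eser", "e_peak", "sep")

__all__ = [
    "MAP_NAMES",
    "TimeIntensityCurve",
    "ParametricMapSet",
    "region_mean_curve",
    "compute_msi",
    "compute_si_slope",
    "compute_e_initial",
    "compute_eser",
    "compute_e_peak",
    "compute_sep",
    "compute_map_set",
]


@dataclass
class TimeIntensityCurve:
    """Region-mean enhancement curve and its peak bookkeeping."""

    si: np.ndarray  # length 9, SI_0..SI_8

    def __post_init__(self) -> None:
        self.si = np.asarray(self.si, dtype=float)
        if self.si.shape != (9,):
            raise ValueError("curve needs exactly 9 samples (SI_0..SI_8)")
        if not np.all(np.isfinite(self.si)):
            raise ValueError("curve values must be finite")

    @property
    def si_mean(self) -> float:
        return float((self.si[1] + self.si[2]) / 2.0)

    @property
    def peak_timepoint(self) -> int:
        """Post-contrast index (1..8) of maximum SI; first max on ties."""
        return int(np.argmax(self.si[1:])) + 1

    @property
    def si_peak(self) -> float:
        return float(self.si[self.peak_timepoint])


@dataclass
class ParametricMapSet:
    """The six maps on one region, plus the degenerate-pixel flags."""

    msi: np.ndarray
    si_slope: np.ndarray
    e_initial: np.ndarray
    eser: np.ndarray
    e_peak: np.ndarray
    sep: np.ndarray
    flags: np.ndarray          # bool raster: any fallback applied at pixel
    peak_timepoint: int
    region: RoiMask

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in MAP_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def n_flagged(self) -> int:
        return int((self.flags & self.region.pixels).sum())


def region_mean_curve(study: DCEStudy, region: RoiMask) -> TimeIntensityCurve:
    if not region:
        raise ValueError("region is empty")
    return TimeIntensityCurve(study.frames[:, region.pixels].mean(axis=1))


def _safe_ratio(num: np.ndarray, den: np.ndarray, scale: float = 100.0):
    """scale·num/den with 0 at den == 0; returns (raster, flag raster)."""
    bad = den == 0
    out = np.zeros(num.shape, dtype=float)
    np.divide(num, den, out=out, where=~bad)
    return scale * out, bad


def compute_msi(study: DCEStudy, region: RoiMask | None = None) -> np.ndarray:
    """Maximum slope of increase: largest consecutive-frame difference."""
    return np.diff(study.frames, axis=0).max(axis=0)


def compute_si_slope(study: DCEStudy, region: RoiMask | None = None):
    si_mean = (study.frames[1] + study.frames[2]) / 2.0
    return _safe_ratio(study.frames[8] - si_mean, si_mean)


def compute_e_initial(study: DCEStudy, region: RoiMask | None = None):
    return _safe_ratio(study.frames[1] - study.frames[0], study.frames[0])


def compute_eser(study: DCEStudy, region: RoiMask | None = None):
    return _safe_ratio(study.frames[1] - study.frames[0],
                       study.frames[2] - study.frames[0])


def compute_sep(study: DCEStudy, region: RoiMask | None = None):
    return _safe_ratio(study.frames[2] - study.frames[0], study.frames[0])


def compute_e_peak(study: DCEStudy, region: RoiMask, per_pixel_peak: bool = False):
    """Peak enhancement relative to baseline.

    By default the peak timepoint is identified once from the
    region-mean time–intensity curve and applied to every pixel; with
    ``per_pixel_peak`` each pixel uses its own post-contrast argmax.
    """
    if per_pixel_peak:
        si_peak = study.frames[1:].max(axis=0)
        peak_t = -1
    else:
        peak_t = region_mean_curve(study, region).peak_timepoint
        si_peak = study.frames[peak_t]
    raster, flags = _safe_ratio(si_peak - study.frames[0], study.frames[0])
    return raster, flags, peak_t


def compute_map_set(
    study: DCEStudy, region: RoiMask, per_pixel_peak: bool = False
) -> ParametricMapSet:
    """All six maps for one region (one consistent peak timepoint)."""
    if not region:
        raise ValueError("region is empty")
    msi = compute_msi(study)
    si_slope, f1 = compute_si_slope(study)
    e_initial, f2 = compute_e_initial(study)
    eser, f3 = compute_eser(study)
    sep, f4 = compute_sep(study)
    e_peak, f5, peak_t = compute_e_peak(study, region, per_pixel_peak)
    return ParametricMapSet(
        msi=msi, si_slope=si_slope, e_initial=e_initial, eser=eser,
        e_peak=e_peak, sep=sep,
        flags=f1 | f2 | f3 | f4 | f5,
        peak_timepoint=peak_t,
        region=region,
    )
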