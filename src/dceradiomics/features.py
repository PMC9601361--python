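"""Four-family radiomic feature bank on (region, map) pairs.

Each of the six kinetic maps, restricted to the intratumoral and
peritumoral ROIs, is normalized between μ ± 3σ of the in-ROI
intensities and quantized to 8 bits (256 gray levels).  From each
quantized (region, map) pair we extract first-order statistics (15) and
GLCM texture descriptors (60); Laws texture-energy (100) and Gabor
filter-bank (240) features are computed on the continuous
ROI-z-normalized map, since filter banks on quantized data alias.  That
is 415 features per (region, map), and 2 regions × 6 maps × 415 = 4980
features per case.

The per-family inventory (15/60/100/240) is this package's convention;
families are named so alternative banks can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

from .core import DCEStudy, RoiMask, RoiSet
from .maps import MAP_NAMES, compute_map_set

N_LEVELS = 256
GLCM_ANGLES = (0, 45, 90, 135)
_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
GABOR_WAVELENGTHS = (2, 4, 6, 8, 10)
GABOR_N_ORIENTATIONS = 8  # step 22.5 degrees
LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
_LAWS_ORDER = ("L5", "E5", "S5", "W5", "R5")

FIRSTORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "range", "sd", "variance",
    "skewness", "kurtosis", "energy", "entropy", "uniformity", "rms",
    "mad", "iqr",
)
GLCM_DESCRIPTORS = (
    "contrast", "dissimilarity", "homogeneity", "asm", "energy",
    "correlation", "entropy", "variance", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy",
    "imc1", "imc2",
)
LAWS_STATS = ("mean", "sd", "skewness", "kurtosis")
GABOR_STATS = ("mean", "sd", "skewness", "kurtosis", "energy", "entropy")

REGION_PREFIXES = ("intra", "peri")

__all__ = [
    "QuantizedRoi",
    "FeatureTable",
    "normalize_quantize",
    "firstorder_features",
    "glcm_features",
    "laws_features",
    "gabor_features",
    "extract_all_features",
    "feature_names",
    "build_feature_table",
    "standardize",
    "N_FEATURES_PER_BLOCK",
    "N_FEATURES_TOTAL",
]

N_FEATURES_PER_BLOCK = (
    len(FIRSTORDER_NAMES)
    + len(GLCM_DESCRIPTORS) * len(GLCM_ANGLES)
    + len(LAWS_VECTORS) ** 2 * len(LAWS_STATS)
    + len(GABOR_WAVELENGTHS) * GABOR_N_ORIENTATIONS * len(GABOR_STATS)
)  # 15 + 60 + 100 + 240 = 415
N_FEATURES_TOTAL = 2 * len(MAP_NAMES) * N_FEATURES_PER_BLOCK  # 4980


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

@dataclass
class QuantizedRoi:
    """8-bit levels on a ROI after μ ± 3σ clipping.

    level = round_half_up(255 · (clip(x, μ−3σ, μ+3σ) − (μ−3σ)) / (6σ)).
    A zero-variance ROI quantizes to the mid level 128 and is flagged.
    """

    levels: np.ndarray        # int raster, -1 outside the ROI
    mask: np.ndarray          # bool raster
    mu: float
    sigma: float
    flagged: bool = False

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def normalize_quantize(map_raster: np.ndarray, region: RoiMask) -> QuantizedRoi:
    """Clip the in-ROI map to μ ± 3σ and quantize to 0..255."""
    mask = region.pixels
    if not mask.any():
        raise ValueError("region is empty")
    vals = np.asarray(map_raster, dtype=float)[mask]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    levels = np.full(mask.shape, -1, dtype=np.int64)
    if sigma == 0.0:
        levels[mask] = N_LEVELS // 2
        return QuantizedRoi(levels, mask, mu, sigma, flagged=True)
    lo = mu - 3.0 * sigma
    clipped = np.clip(vals, lo, mu + 3.0 * sigma)
    levels[mask] = _round_half_up((N_LEVELS - 1) * (clipped - lo) / (6.0 * sigma)).astype(np.int64)
    return QuantizedRoi(levels, mask, mu, sigma)


# ---------------------------------------------------------------------------
# Shared scalar statistics
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray) -> tuple[float, float]:
    """Population skewness m3/m2^1.5 and kurtosis m4/m2^2 (0 if m2 = 0)."""
    m = x.mean()
    d = x - m
    m2 = np.mean(d ** 2)
    if m2 == 0:
        return 0.0, 0.0
    skew = float(np.mean(d ** 3) / m2 ** 1.5)
    kurt = float(np.mean(d ** 4) / m2 ** 2)
    return skew, kurt


def _hist_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# First-order (15)
# ---------------------------------------------------------------------------

def firstorder_features(q: QuantizedRoi) -> dict[str, float]:
    """15 first-order statistics of the in-ROI quantized levels."""
    x = q.roi_levels.astype(float)
    n = x.size
    counts = np.bincount(q.roi_levels, minlength=N_LEVELS)
    p = counts / n
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    skew, kurt = _moments(x)
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(np.ptp(x)),
        "sd": sd,
        "variance": sd ** 2,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x ** 2).sum()),
        "entropy": _hist_entropy(p),
        "uniformity": float((p ** 2).sum()),
        "rms": float(np.sqrt((x ** 2).mean())),
        "mad": float(np.abs(x - mean).mean()),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }


# ---------------------------------------------------------------------------
# GLCM (60)
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedRoi, angle: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix at distance 1.

    Only pixel pairs with both members inside the ROI contribute.
    Returns the L x L probability matrix, or ``None`` if the direction
    has no valid pair.
    """
    dy, dx = _GLCM_OFFSETS[angle]
    levels, mask = q.levels, q.mask
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    y2, x2 = ys + dy, xs + dx
    ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
    ys, xs, y2, x2 = ys[ok], xs[ok], y2[ok], x2[ok]
    ok = mask[y2, x2]
    if not ok.any():
        return None
    i = levels[ys[ok], xs[ok]]
    j = levels[y2[ok], x2[ok]]
    counts = np.bincount(i * N_LEVELS + j, minlength=N_LEVELS * N_LEVELS)
    glcm = counts.reshape(N_LEVELS, N_LEVELS).astype(float)
    glcm = glcm + glcm.T
    return glcm / glcm.sum()


def _haralick(P: np.ndarray) -> dict[str, float]:
    """15 Haralick descriptors of a symmetric normalized GLCM (base-2 logs)."""
    L = P.shape[0]
    ii, jj = np.nonzero(P)
    p = P[ii, jj]
    diff = ii - jj
    px = P.sum(axis=1)  # = py by symmetry
    lv = np.arange(L, dtype=float)
    mu = float((px * lv).sum())
    var = float((px * (lv - mu) ** 2).sum())

    contrast = float((p * diff.astype(float) ** 2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff.astype(float) ** 2)).sum())
    asm = float((p ** 2).sum())
    energy = float(np.sqrt(asm))
    if var > 0:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 1.0
    entropy = _hist_entropy(p)

    psum = np.bincount(ii + jj, weights=p, minlength=2 * L - 1)
    ks = np.arange(2 * L - 1, dtype=float)
    sum_average = float((ks * psum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    sum_entropy = _hist_entropy(psum)

    pdiff = np.bincount(np.abs(diff), weights=p, minlength=L)
    kd = np.arange(L, dtype=float)
    diff_average = float((kd * pdiff).sum())
    difference_variance = float(((kd - diff_average) ** 2 * pdiff).sum())
    difference_entropy = _hist_entropy(pdiff)

    hx = _hist_entropy(px)
    hxy = entropy
    with np.errstate(divide="ignore"):
        logpxpy = np.log2(px[ii] * px[jj])
    hxy1 = float(-(p * logpxpy).sum())
    nz = px > 0
    outer = np.outer(px[nz], px[nz])
    hxy2 = float(-(outer * np.log2(outer)).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "contrast": contrast, "dissimilarity": dissimilarity,
        "homogeneity": homogeneity, "asm": asm, "energy": energy,
        "correlation": correlation, "entropy": entropy, "variance": var,
        "sum_average": sum_average, "sum_variance": sum_variance,
        "sum_entropy": sum_entropy, "difference_variance": difference_variance,
        "difference_entropy": difference_entropy, "imc1": imc1, "imc2": imc2,
    }


def glcm_features(q: QuantizedRoi) -> dict[str, float]:
    """Per-direction Haralick descriptors (4 directions x 15 = 60)."""
    out: dict[str, float] = {}
    for angle in GLCM_ANGLES:
        P = glcm_matrix(q, angle)
        if P is None:  # no valid pair in this direction: zeros, flagged
            desc = {name: 0.0 for name in GLCM_DESCRIPTORS}
        else:
            desc = _haralick(P)
        for name in GLCM_DESCRIPTORS:
            out[f"{name}_a{angle}"] = desc[name]
    return out


# ---------------------------------------------------------------------------
# Laws texture energy (100)
# ---------------------------------------------------------------------------

def laws_kernels() -> dict[str, np.ndarray]:
    """All 25 5x5 Laws masks as outer products of the 1-D vectors."""
    return {
        f"{a}{b}": np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
        for a in _LAWS_ORDER for b in _LAWS_ORDER
    }


def _znormalize_roi(map_raster: np.ndarray, region: RoiMask) -> tuple[np.ndarray, bool]:
    """Center/scale the whole raster by the in-ROI μ and σ.

    A zero-variance ROI leaves the raster unscaled (flagged) so that
    constant inputs keep their physical level rather than collapsing to
    an all-zero field.
    """
    vals = np.asarray(map_raster, dtype=float)
    roi = vals[region.pixels]
    mu = roi.mean()
    sigma = roi.std(ddof=1) if roi.size > 1 else 0.0
    if sigma == 0.0:
        return vals.copy(), True
    return (vals - mu) / sigma, False


def laws_features(map_raster: np.ndarray, region: RoiMask) -> dict[str, float]:
    """Laws texture-energy statistics: 25 masks x 4 ROI statistics.

    The ROI-z-normalized map is convolved (reflect padding) with each
    5x5 mask; the texture-energy image is |response| smoothed by a
    15x15 mean filter; mean/SD/skewness/kurtosis are taken in the ROI.
    """
    field_img, _ = _znormalize_roi(map_raster, region)
    mask = region.pixels
    out: dict[str, float] = {}
    for name, kernel in laws_kernels().items():
        resp = ndimage.convolve(field_img, kernel, mode="reflect")
        energy = ndimage.uniform_filter(np.abs(resp), size=15, mode="reflect")
        x = energy[mask]
        skew, kurt = _moments(x)
        out[f"{name}_mean"] = float(x.mean())
        out[f"{name}_sd"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
        out[f"{name}_skewness"] = skew
        out[f"{name}_kurtosis"] = kurt
    return out


# ---------------------------------------------------------------------------
# Gabor filter bank (240)
# ---------------------------------------------------------------------------

_GABOR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _gabor_kernels() -> dict[tuple[int, int], np.ndarray]:
    """DC-corrected complex Gabor kernels, cached.

    Orientation index k means k·22.5°; θ = 0 responds to gratings whose
    intensity varies along the column (x) axis.
    """
    if not _GABOR_CACHE:
        for wl in GABOR_WAVELENGTHS:
            for k in range(GABOR_N_ORIENTATIONS):
                theta = np.pi * k / GABOR_N_ORIENTATIONS
                kern = gabor_kernel(frequency=1.0 / wl, theta=theta, bandwidth=1.0)
                kern = kern - kern.mean()  # zero DC response
                _GABOR_CACHE[(wl, k)] = kern
    return _GABOR_CACHE


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution with reflect edge handling, output same size."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="reflect")
    return signal.fftconvolve(padded, kernel, mode="valid")


def gabor_features(map_raster: np.ndarray, region: RoiMask) -> dict[str, float]:
    """Gabor magnitude statistics: 5 wavelengths x 8 orientations x 6 stats."""
    field_img, _ = _znormalize_roi(map_raster, region)
    mask = region.pixels
    out: dict[str, float] = {}
    for (wl, k), kern in _gabor_kernels().items():
        resp = _convolve_reflect(field_img, np.real(kern)) + 1j * _convolve_reflect(
            field_img, np.imag(kern)
        )
        mag = np.abs(resp)[mask]
        skew, kurt = _moments(mag)
        mmax = mag.max()
        if mmax > 0:
            hist, _ = np.histogram(mag, bins=64, range=(0.0, mmax))
            ent = _hist_entropy(hist / hist.sum())
        else:
            ent = 0.0
        prefix = f"wl{wl}_o{k}"
        out[f"{prefix}_mean"] = float(mag.mean())
        out[f"{prefix}_sd"] = float(mag.std(ddof=1)) if mag.size > 1 else 0.0
        out[f"{prefix}_skewness"] = skew
        out[f"{prefix}_kurtosis"] = kurt
        out[f"{prefix}_energy"] = float((mag ** 2).mean())
        out[f"{prefix}_entropy"] = ent
    return out


# ---------------------------------------------------------------------------
# Full bank per case
# ---------------------------------------------------------------------------

def _block_features(map_raster: np.ndarray, region: RoiMask) -> dict[str, float]:
    q = normalize_quantize(map_raster, region)
    out = {}
    for name, val in firstorder_features(q).items():
        out[f"firstorder_{name}"] = val
    for name, val in glcm_features(q).items():
        out[f"glcm_{name}"] = val
    for name, val in laws_features(map_raster, region).items():
        out[f"laws_{name}"] = val
    for name, val in gabor_features(map_raster, region).items():
        out[f"gabor_{name}"] = val
    return out


def feature_names() -> list[str]:
    """The 4980 feature names in canonical extraction order."""
    names = []
    for region in REGION_PREFIXES:
        for map_name in MAP_NAMES:
            for f in FIRSTORDER_NAMES:
                names.append(f"{region}_{map_name}_firstorder_{f}")
            for angle in GLCM_ANGLES:
                for f in GLCM_DESCRIPTORS:
                    names.append(f"{region}_{map_name}_glcm_{f}_a{angle}")
            for a in _LAWS_ORDER:
                for b in _LAWS_ORDER:
                    for s in LAWS_STATS:
                        names.append(f"{region}_{map_name}_laws_{a}{b}_{s}")
            for wl in GABOR_WAVELENGTHS:
                for k in range(GABOR_N_ORIENTATIONS):
                    for s in GABOR_STATS:
                        names.append(f"{region}_{map_name}_gabor_wl{wl}_o{k}_{s}")
    return names


def extract_all_features(
    study: DCEStudy, rois: RoiSet, per_pixel_peak: bool = False
) -> pd.Series:
    """Extract the full 4980-feature vector for one case.

    Maps are computed per region so each region's peak timepoint is
    internally consistent; names follow
    ``{region}_{map}_{family}_{feature}`` in deterministic order.
    """
    values: dict[str, float] = {}
    for region_prefix, region in (
        ("intra", rois.intratumoral), ("peri", rois.peritumoral)
    ):
        map_set = compute_map_set(study, region, per_pixel_peak=per_pixel_peak)
        for map_name in MAP_NAMES:
            block = _block_features(map_set[map_name], region)
            for name, val in block.items():
                values[f"{region_prefix}_{map_name}_{name}"] = val
    series = pd.Series(values, name=study.patient_id)
    expected = feature_names()
    series = series.reindex(expected)
    if series.isna().any():
        missing = series.index[series.isna()][:5].tolist()
        raise RuntimeError(f"feature bank incomplete, e.g. {missing}")
    return series


# ---------------------------------------------------------------------------
# Cohort feature table and standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Patients x features table with optional z-standardization state."""

    df: pd.DataFrame
    standardized: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None
    zero_sd_columns: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.df.shape[1]

    def region_columns(self, region_prefix: str) -> list[str]:
        return [c for c in self.df.columns if c.startswith(region_prefix + "_")]


def build_feature_table(studies, roi_sets, per_pixel_peak: bool = False) -> FeatureTable:
    """Extract features for every study and stack them into a table."""
    rows = [
        extract_all_features(study, rois, per_pixel_peak=per_pixel_peak)
        for study, rois in zip(studies, roi_sets)
    ]
    return FeatureTable(pd.DataFrame(rows))


def standardize(table: FeatureTable, training_rows) -> FeatureTable:
    """z-score every column using the training rows' mean and SD.

    ``training_rows`` are integer row positions.  Validation rows are
    transformed with the training μ/SD, never their own.  Zero-SD
    columns are set to 0 and recorded in ``zero_sd_columns``.
    """
    idx = np.asarray(training_rows, dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 training rows")
    # Work on a C-contiguous array so the reduction order (and hence the
    # float result) does not depend on the frame's internal block layout.
    values = np.ascontiguousarray(table.df.to_numpy(dtype=float))
    train = values[idx]
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    means = pd.Series(mu, index=table.df.columns)
    sds = pd.Series(sd, index=table.df.columns)
    zero = means.index[sd == 0].tolist()
    safe = np.where(sd == 0, 1.0, sd)
    out = (values - mu) / safe
    out[:, sd == 0] = 0.0
    df = pd.DataFrame(out, index=table.df.index, columns=table.df.columns)
    return FeatureTable(
        df=df, standardized=True, means=means, sds=sds, zero_sd_columns=zero
    )
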