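"""Seeded synthetic DCE-MRI cohorts with known, plantable class structure.

Patient data behind the analysis this package implements are not
publicly deposited, so every downstream stage is exercised on simulated
studies.  Two generators are provided:

* an image-level generator (:func:`generate_study`,
  :func:`generate_cohort`) producing 9-frame DCE time series with an
  elliptical lesion whose wash-in/wash-out kinetics depend on receptor
  class, an independently informative peritumoral rim, a breast
  parenchyma mask, spatial texture and additive acquisition noise;

* a feature-level cohort simulator (:func:`simulate_feature_cohort`)
  that emulates the statistical structure the signature-selection
  stages consume — a patients x features table with planted intra- and
  peritumoral effects, a noisy second-reader replicate, and correlated
  ER/PR labels — at cohort sizes where running the full image pipeline
  per patient would be pointless for testing the selection machinery.

Everything is a pure function of (config, seed): identical inputs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DCEStudy, RoiMask, N_FRAMES

__all__ = [
    "KineticParams",
    "SyntheticConfig",
    "FeatureCohortConfig",
    "generate_study",
    "generate_cohort",
    "simulate_second_reader",
    "simulate_feature_cohort",
    "enhancement_curve",
    "joint_label_probs",
]


@dataclass
class KineticParams:
    """Per-class enhancement kinetics: SI(t) = SI0·[1 + A(1-e^(-αt))e^(-βt)].

    ``amplitude`` (A) is the dimensionless wash-in amplitude, ``wash_in``
    (α, 1/frame) the uptake rate, ``wash_out`` (β, 1/frame) the decay
    rate; ``*_sd`` are between-patient standard deviations.
    """

    amplitude: float
    wash_in: float
    wash_out: float
    amplitude_sd: float = 0.15
    wash_in_sd: float = 0.1
    wash_out_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("wash_in", "wash_out", "amplitude_sd", "wash_in_sd", "wash_out_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticConfig:
    """Image-level cohort configuration.

    Defaults emulate the acquisition regime of the modelled study: a
    1024x1024 matrix over a 340 mm field of view gives 0.332 mm/px; we
    simulate a 128 px crop around the lesion at that spacing.  The
    positive fraction defaults to 0.66 (the ER-positive prevalence of
    the modelled cohort) and ER/PR are associated with odds ratio 6.
    """

    n_patients: int = 40
    image_size: int = 128
    pixel_spacing_mm: float = 340.0 / 1024.0
    positive_fraction: float = 0.66
    er_pr_odds_ratio: float = 6.0
    kinetics_positive: KineticParams = field(
        default_factory=lambda: KineticParams(amplitude=2.2, wash_in=1.4, wash_out=0.05)
    )
    kinetics_negative: KineticParams = field(
        default_factory=lambda: KineticParams(amplitude=1.6, wash_in=0.7, wash_out=0.12)
    )
    # Rim enhances with amplitude rim_amplitude * (1 + peritumoral_effect)
    # in the positive class, rim_amplitude in the negative class.
    rim_amplitude: float = 0.6
    peritumoral_effect: float = 0.3
    rim_width_mm: float = 4.0
    parenchyma_amplitude: float = 0.2
    lesion_radius_px: tuple[float, float] = (10.0, 18.0)
    baseline_intensity: float = 100.0
    texture_correlation_px: float = 4.0
    texture_amplitude: float = 0.15
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        for name in ("noise_sd", "texture_amplitude", "parenchyma_amplitude",
                     "rim_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if isinstance(self.kinetics_positive, dict):
            self.kinetics_positive = KineticParams(**self.kinetics_positive)
        if isinstance(self.kinetics_negative, dict):
            self.kinetics_negative = KineticParams(**self.kinetics_negative)
        max_radius = max(self.lesion_radius_px)
        rim_px = self.rim_width_mm / self.pixel_spacing_mm
        # placement margin in generate_study is radius + rim + 4 px
        if 2 * (max_radius + rim_px + 4) >= self.image_size:
            raise ValueError("lesion plus rim does not fit in the image")

    def to_dict(self) -> dict:
        return asdict(self)


def enhancement_curve(t: np.ndarray, amplitude: float, wash_in: float,
                      wash_out: float) -> np.ndarray:
    """Relative enhancement f(t) = A·(1 − e^(−αt))·e^(−βt); f(0) = 0."""
    t = np.asarray(t, dtype=float)
    return amplitude * (1.0 - np.exp(-wash_in * t)) * np.exp(-wash_out * t)


def joint_label_probs(p: float, odds_ratio: float) -> np.ndarray:
    """2x2 joint cell probabilities for two binary labels.

    Both marginals equal ``p``; the association is set by ``odds_ratio``
    (Plackett construction).  Returns [[p00, p01], [p10, p11]].
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if odds_ratio == 1.0:
        p11 = p * p
    else:
        s = 1.0 + 2.0 * p * (odds_ratio - 1.0)
        p11 = (s - np.sqrt(s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p * p)) / (
            2.0 * (odds_ratio - 1.0)
        )
    p10 = p01 = p - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([[p00, p01], [p10, p11]])
    if np.any(probs < -1e-12):
        raise ValueError("invalid marginal/odds-ratio combination")
    return np.clip(probs, 0.0, 1.0)


def _patient_rng(seed: int, patient_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, patient_index))
    )


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      correlation_px: float, amplitude: float) -> np.ndarray:
    """Zero-mean Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    if correlation_px > 0:
        smooth = ndimage.gaussian_filter(white, correlation_px, mode="wrap")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
    else:
        smooth = white
    return amplitude * smooth


def generate_study(config: SyntheticConfig, patient_index: int) -> DCEStudy:
    """Simulate one patient's 9-frame DCE study.

    The lesion is a randomly oriented ellipse; each lesion pixel follows
    the class kinetic curve modulated by a spatially correlated texture
    field.  Rim pixels (within ``rim_width_mm`` of the lesion boundary,
    inside the breast) enhance with a class-dependent amplitude;
    parenchyma enhances weakly; air outside the breast does not enhance.
    Ground truth (lesion mask, breast mask, seed box, kinetic draws) is
    recorded in ``study.truth``.
    """
    if patient_index >= config.n_patients:
        raise ValueError("patient_index out of range")
    rng = _patient_rng(config.seed, patient_index)
    n = config.image_size
    yy, xx = np.mgrid[0:n, 0:n]

    # --- labels (joint ER/PR draw, same marginal, configurable OR) ---
    probs = joint_label_probs(config.positive_fraction, config.er_pr_odds_ratio)
    cell = rng.choice(4, p=probs.ravel())
    er_label, pr_label = int(cell // 2), int(cell % 2)
    kin = config.kinetics_positive if er_label else config.kinetics_negative

    # --- geometry ---
    rim_px = config.rim_width_mm / config.pixel_spacing_mm
    r_lo, r_hi = config.lesion_radius_px
    a = rng.uniform(r_lo, r_hi)
    b = rng.uniform(r_lo, r_hi)
    margin = max(a, b) + rim_px + 4
    cy = rng.uniform(margin, n - margin)
    cx = rng.uniform(margin, n - margin)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    lesion = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not lesion.any():
        raise ValueError("lesion larger than image or degenerate; reject config")

    # Breast mask: large ellipse containing lesion + rim with slack.
    breast = ((xx - n / 2) / (0.47 * n)) ** 2 + ((yy - n / 2) / (0.47 * n)) ** 2 <= 1.0
    ring_support = ndimage.binary_dilation(
        lesion, structure=_disk(int(round(rim_px)))
    )
    breast |= ring_support  # guarantee rim never leaves the breast

    dist_out = ndimage.distance_transform_edt(~lesion)
    rim = (~lesion) & (dist_out <= rim_px) & breast

    # --- per-patient kinetic draws ---
    A = max(0.0, rng.normal(kin.amplitude, kin.amplitude_sd))
    alpha = max(0.0, rng.normal(kin.wash_in, kin.wash_in_sd))
    beta = max(0.0, rng.normal(kin.wash_out, kin.wash_out_sd))
    rim_gain = config.rim_amplitude * (
        1.0 + config.peritumoral_effect * (1 if er_label else 0)
    )

    texture = _correlated_field(
        rng, (n, n), config.texture_correlation_px, config.texture_amplitude
    )

    # --- baseline (pre-contrast) image ---
    si0 = np.full((n, n), config.baseline_intensity, dtype=float)
    si0 += _correlated_field(rng, (n, n), 12.0, 0.05 * config.baseline_intensity)
    si0[~breast] = 0.1 * config.baseline_intensity
    si0 = np.clip(si0, 1.0, None)

    # Lesion pixels follow the class kinetic curve; rim and parenchyma
    # follow fixed background kinetics so that, with
    # peritumoral_effect = 0, the rim carries no class information
    # beyond noise (only its amplitude is class-modulated).
    amp_lesion = np.zeros((n, n))
    amp_lesion[lesion] = A
    amp_bg = np.zeros((n, n))
    amp_bg[breast & ~lesion] = config.parenchyma_amplitude
    amp_bg[rim] = rim_gain
    amp_lesion = amp_lesion * (1.0 + texture)
    amp_bg = amp_bg * (1.0 + texture)

    t = np.arange(N_FRAMES, dtype=float)
    shape_lesion = (1.0 - np.exp(-alpha * t)) * np.exp(-beta * t)  # f(t)/A
    shape_bg = (1.0 - np.exp(-1.0 * t)) * np.exp(-0.08 * t)
    frames = si0[None] * (
        1.0
        + amp_lesion[None] * shape_lesion[:, None, None]
        + amp_bg[None] * shape_bg[:, None, None]
    )
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)

    # Seed box for semi-automatic segmentation: lesion bbox padded 4 px.
    ys, xs = np.nonzero(lesion)
    pad = 4
    seed_box = (
        max(0, ys.min() - pad), min(n, ys.max() + pad + 1),
        max(0, xs.min() - pad), min(n, xs.max() + pad + 1),
    )

    return DCEStudy(
        patient_id=f"P{patient_index:04d}",
        frames=frames,
        pixel_spacing_mm=config.pixel_spacing_mm,
        er_label=er_label,
        pr_label=pr_label,
        acquisition_index=patient_index,
        truth={
            "lesion_mask": lesion,
            "breast_mask": breast,
            "rim_mask": rim,
            "seed_box": seed_box,
            "amplitude": A,
            "wash_in": alpha,
            "wash_out": beta,
            "rim_gain": rim_gain,
        },
    )


def generate_cohort(config: SyntheticConfig) -> list[DCEStudy]:
    """Simulate the full cohort, ordered by acquisition index."""
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    return [generate_study(config, i) for i in range(config.n_patients)]


def simulate_second_reader(mask: RoiMask, jitter_px: int, seed: int) -> RoiMask:
    """Simulate a second reader's segmentation of the same lesion.

    The boundary is perturbed by thresholding the signed distance field
    at a smooth random offset bounded by ``jitter_px``; the result is
    reduced to its largest connected component with holes filled, so
    connectivity is preserved.  ``jitter_px = 0`` returns the input
    unchanged.
    """
    if not mask:
        raise ValueError("mask is empty")
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    if jitter_px == 0:
        return RoiMask(mask.pixels.copy(), mask.region_tag, mask.pixel_spacing_mm)
    rng = np.random.default_rng(seed)
    px = mask.pixels
    # Signed distance: negative inside the mask, positive outside.
    sd = ndimage.distance_transform_edt(~px) - ndimage.distance_transform_edt(px)
    offset = _correlated_field(rng, px.shape, 3.0, float(jitter_px))
    offset = np.clip(offset, -jitter_px, jitter_px)
    perturbed = sd + offset < 0
    labels, n_comp = ndimage.label(perturbed, structure=np.ones((3, 3)))
    if n_comp == 0:
        raise ValueError("perturbation emptied the mask")
    largest = np.argmax(ndimage.sum_labels(perturbed, labels, range(1, n_comp + 1))) + 1
    out = ndimage.binary_fill_holes(labels == largest)
    return RoiMask(out, mask.region_tag, mask.pixel_spacing_mm)


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return x * x + y * y <= radius * radius


# ---------------------------------------------------------------------------
# Feature-level cohort simulator
# ---------------------------------------------------------------------------

@dataclass
class FeatureCohortConfig:
    """Feature-level cohort with planted regional class effects.

    Emulates what the image pipeline hands to the signature stages: an
    (unstandardized) patients x features table split into intra- and
    peritumoral blocks, a second-reader replicate whose per-feature
    noise makes a configurable fraction of features unstable
    (ICC <= 0.8), and jointly sampled ER/PR labels.  Per endpoint,
    ``n_informative`` features in each region carry a mean shift of
    ``effect_size`` (in within-class SD units) for positive patients.
    """

    n_patients: int = 300
    n_intra: int = 80
    n_peri: int = 80
    n_informative: int = 4
    effect_size: float = 0.7
    positive_fraction: float = 0.66
    er_pr_odds_ratio: float = 6.0
    unstable_fraction: float = 0.2
    reader_noise_stable: float = 0.15
    reader_noise_unstable: float = 1.5
    feature_scale_range: tuple[float, float] = (0.5, 20.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0.0 <= self.unstable_fraction < 1.0:
            raise ValueError("unstable_fraction must be in [0, 1)")
        need = 2 * self.n_informative
        if need > min(self.n_intra, self.n_peri):
            raise ValueError("not enough features for the planted effects")


def simulate_feature_cohort(
    config: FeatureCohortConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (reader1 table, reader2 table, labels).

    Column names follow the pipeline convention
    ``{intra|peri}_f{index:03d}``; informative columns additionally end
    in ``_er`` / ``_pr``.  The labels frame has columns
    ``er_label``, ``pr_label``, ``acquisition_index`` indexed like the
    tables.  Features carry heterogeneous scales (the z-standardization
    stage is expected to remove them).
    """
    rng = np.random.default_rng(seed)
    n = config.n_patients
    probs = joint_label_probs(config.positive_fraction, config.er_pr_odds_ratio)
    cells = rng.choice(4, size=n, p=probs.ravel())
    er = (cells // 2).astype(int)
    pr = (cells % 2).astype(int)

    blocks, names = [], []
    stable_noise_sd = []
    for region, n_feat in (("intra", config.n_intra), ("peri", config.n_peri)):
        x = rng.standard_normal((n, n_feat))
        k = config.n_informative
        # First k features per region respond to ER, next k to PR.
        x[:, :k] += config.effect_size * er[:, None]
        x[:, k:2 * k] += config.effect_size * pr[:, None]
        unstable = rng.random(n_feat) < config.unstable_fraction
        noise_sd = np.where(
            unstable, config.reader_noise_unstable, config.reader_noise_stable
        )
        for j in range(n_feat):
            suffix = "_er" if j < k else ("_pr" if j < 2 * k else "")
            names.append(f"{region}_f{j:03d}{suffix}")
        blocks.append(x)
        stable_noise_sd.append(noise_sd)

    x = np.hstack(blocks)
    noise_sd = np.concatenate(stable_noise_sd)
    scale = rng.uniform(*config.feature_scale_range, size=x.shape[1])
    shift = rng.normal(0.0, 5.0, size=x.shape[1])
    x1 = x * scale + shift
    x2 = (x + rng.standard_normal(x.shape) * noise_sd) * scale + shift

    index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    r1 = pd.DataFrame(x1, index=index, columns=names)
    r2 = pd.DataFrame(x2, index=index, columns=names)
    labels = pd.DataFrame(
        {"er_label": er, "pr_label": pr, "acquisition_index": np.arange(n)},
        index=index,
    )
    return r1, r2, labels
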