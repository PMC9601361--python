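import numpy as np
import pytest

from dceradiomics.core import DCEStudy, RoiMask
from dceradiomics.segmentation import build_roi_set
from dceradiomics.synthetic import KineticParams, SyntheticConfig, generate_study


def small_config(**overrides) -> SyntheticConfig:
    """A 64 px cohort configuration that keeps tests fast."""
    defaults = dict(
        n_patients=8,
        image_size=64,
        lesion_radius_px=(6.0, 9.0),
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def demo_config() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def demo_study(demo_config) -> DCEStudy:
    return generate_study(demo_config, 0)


@pytest.fixture(scope="session")
def demo_rois(demo_study):
    return build_roi_set(
        demo_study, demo_study.truth["seed_box"], demo_study.truth["breast_mask"]
    )


def study_from_curve(curve, shape=(4, 4), spacing=1.0) -> DCEStudy:
    """Constant-per-frame study whose every pixel follows ``curve``."""
    curve = np.asarray(curve, dtype=float)
    frames = np.broadcast_to(curve[:, None, None], (9, *shape)).copy()
    return DCEStudy(
        patient_id="toy",
        frames=frames,
        pixel_spacing_mm=spacing,
        er_label=0,
        pr_label=0,
        acquisition_index=0,
    )


def full_region(shape=(4, 4), spacing=1.0) -> RoiMask:
    return RoiMask(np.ones(shape, dtype=bool), "intratumoral", spacing)
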