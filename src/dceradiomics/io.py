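"""Reading and writing cohorts, masks, feature tables and models.

Per-patient frames are stored as one 3-D NIfTI (third axis = time);
the cohort manifest is a CSV with patient id, acquisition index,
labels, seed box and file paths; configs travel as YAML.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import DCEStudy, RoiMask
from .features import FeatureTable
from .synthetic import SyntheticConfig

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_mask",
    "load_mask",
    "save_feature_table",
    "load_feature_table",
    "save_config",
    "load_config",
]

MANIFEST_NAME = "manifest.csv"


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["lesion_radius_px"] = tuple(data["lesion_radius_px"])
    return SyntheticConfig(**data)


def save_cohort(studies: list[DCEStudy], outdir) -> pathlib.Path:
    """Write NIfTI frame stacks plus a manifest CSV; returns manifest path."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in studies:
        fname = f"{study.patient_id}_frames.nii.gz"
        # axes (x, y, t); spacing in mm, frame axis unit-less
        affine = np.diag([study.pixel_spacing_mm, study.pixel_spacing_mm, 1.0, 1.0])
        img = nib.Nifti1Image(
            np.transpose(study.frames, (1, 2, 0)).astype(np.float32), affine
        )
        nib.save(img, outdir / fname)
        row = {
            "patient_id": study.patient_id,
            "acquisition_index": study.acquisition_index,
            "er_label": study.er_label,
            "pr_label": study.pr_label,
            "pixel_spacing_mm": study.pixel_spacing_mm,
            "frames_path": fname,
        }
        if "seed_box" in study.truth:
            r0, r1, c0, c1 = study.truth["seed_box"]
            row.update(box_r0=r0, box_r1=r1, box_c0=c0, box_c1=c1)
        if "breast_mask" in study.truth:
            mname = f"{study.patient_id}_breast.nii.gz"
            save_mask(
                RoiMask(study.truth["breast_mask"], "breast", study.pixel_spacing_mm),
                outdir / mname,
            )
            row["breast_mask_path"] = mname
        rows.append(row)
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list[DCEStudy]:
    manifest_path = pathlib.Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    studies = []
    for _, row in df.iterrows():
        frames = np.asarray(nib.load(base / row["frames_path"]).dataobj)
        frames = np.transpose(frames, (2, 0, 1)).astype(float)
        truth = {}
        if "box_r0" in row and not pd.isna(row["box_r0"]):
            truth["seed_box"] = tuple(
                int(row[k]) for k in ("box_r0", "box_r1", "box_c0", "box_c1")
            )
        if "breast_mask_path" in row and isinstance(row["breast_mask_path"], str):
            truth["breast_mask"] = load_mask(base / row["breast_mask_path"], "breast").pixels
        studies.append(
            DCEStudy(
                patient_id=str(row["patient_id"]),
                frames=frames,
                pixel_spacing_mm=float(row["pixel_spacing_mm"]),
                er_label=int(row["er_label"]),
                pr_label=int(row["pr_label"]),
                acquisition_index=int(row["acquisition_index"]),
                truth=truth,
            )
        )
    studies.sort(key=lambda s: s.acquisition_index)
    return studies


def save_mask(mask: RoiMask, path) -> None:
    affine = np.diag([mask.pixel_spacing_mm, mask.pixel_spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(mask.pixels.astype(np.uint8)[..., None], affine)
    nib.save(img, str(path))


def load_mask(path, region_tag: str, pixel_spacing_mm: float | None = None) -> RoiMask:
    img = nib.load(str(path))
    pixels = np.asarray(img.dataobj)[..., 0] > 0
    if pixel_spacing_mm is None:
        pixel_spacing_mm = float(abs(img.affine[0, 0])) or 1.0
    return RoiMask(pixels, region_tag, pixel_spacing_mm)


def save_feature_table(table: FeatureTable, csv_path) -> None:
    """CSV of values plus a JSON sidecar with standardization state."""
    csv_path = pathlib.Path(csv_path)
    table.df.to_csv(csv_path)
    sidecar = {
        "standardized": table.standardized,
        "zero_sd_columns": table.zero_sd_columns,
        "means": None if table.means is None else table.means.to_dict(),
        "sds": None if table.sds is None else table.sds.to_dict(),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_table(csv_path) -> FeatureTable:
    csv_path = pathlib.Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    table = FeatureTable(df)
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        table.standardized = sidecar["standardized"]
        table.zero_sd_columns = sidecar["zero_sd_columns"]
        if sidecar["means"] is not None:
            table.means = pd.Series(sidecar["means"])
            table.sds = pd.Series(sidecar["sds"])
    return table
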