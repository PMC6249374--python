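"""File-format plumbing: NIfTI masks, TSV tables, JSON results, YAML config.

Conventions
-----------
* Volumes are NIfTI-1 (``.nii`` / ``.nii.gz``); probability maps are written
  float32, masks uint8.
* Mask filenames follow ``{subject_id}_{hemisphere}_{structure}.nii[.gz]``;
  conformation metadata travels in a TSV sidecar (``cohort.tsv``) keyed by
  subject_id + hemisphere, never in NIfTI headers.
* Cohort tables: one row per subject x hemisphere with columns subject_id,
  age, sex, hemisphere, hemisphere_volume, hemisphere_surface,
  conformation_type.
* Morphometry tables: subject_id, hemisphere, sulcus, max_depth, mean_depth,
  length, conformation_type (the layout of per-sulcus depth/length tables).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volume import LabeledVolume, SubjectMask

log = logging.getLogger("mtlatlas")

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "hemisphere",
    "hemisphere_volume",
    "hemisphere_surface",
    "conformation_type",
]
MORPHOMETRY_COLUMNS = [
    "subject_id",
    "hemisphere",
    "sulcus",
    "max_depth",
    "mean_depth",
    "length",
    "conformation_type",
]

_MASK_NAME = re.compile(
    r"^(?P<subject>.+)_(?P<hemi>[LR])_(?P<structure>[A-Za-z]+)\.nii(\.gz)?$"
)


def write_volume(vol: LabeledVolume, path, dtype=np.float32) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    nib.save(img, str(path))
    return path


def read_volume(path) -> LabeledVolume:
    img = nib.load(str(path))
    if img.affine is None:
        raise ValueError(f"{path}: volume has no affine")
    return LabeledVolume(np.asanyarray(img.dataobj), img.affine)


def write_mask(mask: SubjectMask, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = f"{mask.subject_id}_{mask.hemisphere}_{mask.structure}.nii.gz"
    return write_volume(mask.volume, out_dir / name, dtype=np.uint8)


def read_mask(path, cohort: pd.DataFrame | None = None) -> SubjectMask:
    """Read one binary mask; metadata parsed from the filename convention.

    If a cohort table is given, the hemisphere's conformation type is looked
    up by (subject_id, hemisphere); otherwise it is left unknown.

    Raises
    ------
    ValueError
        If the volume is not binary (after rounding tolerance 1e-6), is
        empty, or the filename does not encode subject/hemisphere/structure.
    """
    path = Path(path)
    m = _MASK_NAME.match(path.name)
    if m is None:
        raise ValueError(
            f"{path.name}: mask filename must match "
            "'{subject}_{L|R}_{structure}.nii[.gz]'"
        )
    vol = read_volume(path)
    ctype = 0
    if cohort is not None:
        row = cohort[
            (cohort.subject_id == m["subject"]) & (cohort.hemisphere == m["hemi"])
        ]
        if len(row):
            ctype = int(row.conformation_type.iloc[0])
    return SubjectMask(
        subject_id=m["subject"],
        hemisphere=m["hemi"],
        structure=m["structure"],
        volume=vol,
        conformation_type=ctype,
    )


def read_mask_dir(mask_dir, cohort: pd.DataFrame | None = None) -> list[SubjectMask]:
    """Read every NIfTI mask in a directory, sorted by filename."""
    mask_dir = Path(mask_dir)
    paths = sorted(mask_dir.glob("*.nii")) + sorted(mask_dir.glob("*.nii.gz"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks in {mask_dir}")
    return [read_mask(p, cohort) for p in paths]


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------
def write_cohort_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[COHORT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_morphometry_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[MORPHOMETRY_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_morphometry_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(MORPHOMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"morphometry table missing columns: {sorted(missing)}")
    bad = df[(df.max_depth <= 0) | (df.mean_depth <= 0) | (df.length <= 0)]
    if len(bad):
        raise ValueError("morphometry measurements must be strictly positive")
    if np.any(df.mean_depth > df.max_depth + 1e-9):
        raise ValueError("mean_depth exceeds max_depth in morphometry table")
    return df


# ----------------------------------------------------------------------
# JSON / YAML
# ----------------------------------------------------------------------
class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(payload, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
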