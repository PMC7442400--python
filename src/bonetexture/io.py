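"""Reading and writing volumes, masks, cohort tables and reports.

Volumes and segmentation masks travel as NIfTI-1 (``.nii`` / ``.nii.gz``)
files; cohort covariates, feature tables and statistical reports are plain
CSV with a header row.  All voxel indexing is 0-based in index space and no
resampling or reorientation is ever performed: texture is defined on the
acquired voxel lattice, so the grid is taken exactly as stored.  Masks use
the "nonzero = inside" convention.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    CohortParseError,
    DegenerateVoiError,
    DimensionalityError,
    GeometryError,
    SchemaError,
)

__all__ = [
    "ImageVolume",
    "VoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_report",
    "read_features",
    "write_features",
    "REPORT_FLOAT_FORMAT",
]

#: Fixed float formatting for every CSV report, so identical inputs always
#: produce byte-identical files.  12 significant digits round-trip well
#: below the 1e-9 fidelity contract.
REPORT_FLOAT_FORMAT = "%.12g"

COHORT_COLUMNS = ("id", "age", "sex", "bmi", "bmd")


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar intensity grid with its physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise DimensionalityError(
                f"volume must be 3-D, got {data.ndim}-D with shape {data.shape}"
            )
        if data.size == 0 or min(data.shape) < 1:
            raise DimensionalityError("volume must have at least one voxel per axis")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class VoiMask:
    """A boolean volume-of-interest grid, same shape as its companion volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"mask must be 3-D, got {data.ndim}-D with shape {data.shape}"
            )
        object.__setattr__(self, "data", data.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _load_nifti_3d(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(os.fspath(path))
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D NIfTI image, got shape {img.shape}"
        )
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3-D NIfTI intensity volume.

    The grid is returned in index space with spacing taken from the header;
    no resampling or reorientation is performed.
    """
    data, zooms = _load_nifti_3d(path)
    return ImageVolume(data=data, spacing=zooms)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal (spacing) affine."""
    affine = np.diag((*volume.spacing, 1.0))
    nib.save(nib.Nifti1Image(volume.data, affine), os.fspath(path))


def read_mask(path: str | os.PathLike, volume: ImageVolume) -> VoiMask:
    """Read a segmentation mask and check it against its companion volume.

    Any nonzero stored value maps to True (inside the VOI).
    """
    data, _ = _load_nifti_3d(path)
    if data.shape != volume.shape:
        raise GeometryError(
            f"{path}: mask shape {data.shape} does not match volume shape {volume.shape}"
        )
    mask = VoiMask(data != 0)
    if mask.n_voxels == 0:
        raise DegenerateVoiError(f"{path}: mask contains no nonzero voxel")
    return mask


def write_mask(
    mask: VoiMask, path: str | os.PathLike, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    affine = np.diag((*spacing, 1.0))
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), os.fspath(path))


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a subject covariate table.

    Requires columns ``id, age, sex, bmi, bmd`` (extra columns are
    preserved).  Ids must be unique; age/bmi/bmd must be positive numbers;
    sex must be ``F`` or ``M``.  Missing covariates are hard errors — the
    association analysis assumes a complete cohort.
    """
    table = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = table["id"][table["id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate subject id(s) {sorted(set(dup))}")
    for col in ("age", "bmi", "bmd"):
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            bad = table.loc[values.isna(), "id"].tolist()
            raise CohortParseError(
                f"{path}: non-numeric or missing {col} for subject(s) {bad}"
            )
        if (values <= 0).any():
            bad = table.loc[values <= 0, "id"].tolist()
            raise CohortParseError(f"{path}: non-positive {col} for subject(s) {bad}")
        table[col] = values.astype(float)
    bad_sex = ~table["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise CohortParseError(
            f"{path}: sex must be 'F' or 'M' for subject(s) "
            f"{table.loc[bad_sex, 'id'].tolist()}"
        )
    return table


def _rows_to_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    records = []
    for row in rows:
        if dataclasses.is_dataclass(row):
            records.append(dataclasses.asdict(row))
        else:
            records.append(dict(row))
    return pd.DataFrame.from_records(records)


def write_report(rows, path: str | os.PathLike) -> None:
    """Write association or concordance results as a deterministic CSV.

    Column order follows the input frame; floats are rendered with a fixed
    12-significant-digit format so reruns on identical inputs are
    byte-identical and round-trip reads agree to well below 1e-9.
    """
    frame = _rows_to_frame(rows)
    if frame.empty:
        raise SchemaError("refusing to write an empty report")
    frame.to_csv(
        os.fspath(path),
        index=False,
        float_format=REPORT_FLOAT_FORMAT,
        lineterminator="\n",
    )


def write_features(features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-subject feature table (id + attribute columns) as CSV."""
    write_report(features, path)


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-subject feature table written by :func:`write_features`."""
    table = pd.read_csv(path, dtype={"id": str})
    if "id" not in table.columns:
        raise SchemaError(f"{path}: feature table must have an 'id' column")
    dup = table["id"][table["id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate subject id(s) {sorted(set(dup))}")
    return table
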