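"""NIfTI / CSV round-trip helpers.

Files on disk use the community-standard formats: volumes as NIfTI-1
(optionally gzipped), atlases as NIfTI plus a region-table CSV
(``id,name,is_reference``), subject labels as CSV
(``subject_id,label,subgroup``) with UTF-8 encoding, comma delimiter and a
header row.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import AtlasVolume, MetabolismVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "read_labels",
    "write_labels",
]


def read_volume(path: str | Path, subject_id: str = "") -> MetabolismVolume:
    """Load a 3-D NIfTI volume.

    Raises
    ------
    ValueError
        If the image is not 3-D (the path is named in the message).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D NIfTI image, got {data.ndim}-D")
    return MetabolismVolume(
        data=np.asarray(data, dtype=np.float64),
        affine=np.asarray(img.affine),
        subject_id=subject_id or path.name.split(".")[0],
    )


def write_volume(volume: MetabolismVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def read_atlas(nifti_path: str | Path, table_path: str | Path) -> AtlasVolume:
    nifti_path = Path(nifti_path)
    img = nib.load(str(nifti_path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{nifti_path}: expected a 3-D label image, got {labels.ndim}-D")
    regions = pd.read_csv(table_path)
    regions["is_reference"] = regions["is_reference"].astype(bool)
    return AtlasVolume(
        labels=np.rint(labels).astype(np.int32),
        regions=regions,
        affine=np.asarray(img.affine),
    )


def write_atlas(atlas: AtlasVolume, nifti_path: str | Path, table_path: str | Path) -> None:
    nifti_path = Path(nifti_path)
    nifti_path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(nifti_path))
    atlas.regions.to_csv(table_path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read the subject table (``subject_id,label,subgroup``)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: labels CSV missing columns {sorted(missing)}")
    df["label"] = df["label"].astype(int)
    if not df["label"].isin([0, 1]).all():
        raise ValueError(f"{path}: labels must be 0/1")
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
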