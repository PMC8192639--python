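"""In-memory containers for template-space volumes and atlas parcellations.

All volumes are assumed to be already warped to a common template grid
(e.g. MNI space for real data): spatial registration is an upstream
responsibility.  Voxel indices are 0-based throughout; millimetre
coordinates are obtained only through the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetabolismVolume", "AtlasVolume"]


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class MetabolismVolume:
    """A 3-D scalar image (e.g. an FDG-PET uptake map) with subject metadata.

    Parameters
    ----------
    data : ndarray of shape (nx, ny, nz)
        Voxel intensities in arbitrary units; must be finite.
    affine : ndarray of shape (4, 4)
        Voxel-index to millimetre transform (NIfTI convention).
    subject_id : str
        Identifier used as the join key across labels/predictions tables.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3-D, got {self.data.ndim}-D "
                f"(shape {self.data.shape})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation with a region-name table.

    ``labels`` assigns each voxel a non-negative integer: 0 is background,
    positive ids index rows of ``regions`` (columns ``id``, ``name``,
    ``is_reference``).  Reference regions (pons, cerebellum) are the
    denominators of intensity normalization and SUVR computation.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        required = {"id", "name", "is_reference"}
        if not required.issubset(self.regions.columns):
            raise ValueError(f"region table must have columns {sorted(required)}")
        if self.regions["id"].duplicated().any():
            raise ValueError("duplicate region ids in region table")
        if self.regions["name"].duplicated().any():
            raise ValueError("duplicate region names in region table")
        if (self.regions["id"] <= 0).any():
            raise ValueError("region ids must be positive (0 is background)")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    def id_of(self, name: str) -> int:
        row = self.regions.loc[self.regions["name"] == name, "id"]
        if row.empty:
            raise KeyError(f"region {name!r} not found in atlas")
        return int(row.iloc[0])

    def name_of(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["id"] == region_id, "name"]
        if row.empty:
            raise KeyError(f"region id {region_id} not found in atlas")
        return str(row.iloc[0])

    def mask(self, name: str) -> np.ndarray:
        """Boolean voxel mask of the named region."""
        return self.labels == self.id_of(name)

    def brain_mask(self) -> np.ndarray:
        """All labelled (non-background) voxels."""
        return self.labels > 0
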