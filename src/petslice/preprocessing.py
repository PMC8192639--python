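"""Reference-region intensity normalization and orthogonal slice decomposition.

FDG uptake maps carry a subject-specific global scale (injected dose, body
weight, scanner calibration).  Dividing every voxel by the mean intensity of
a reference region with preserved metabolism — the pons by convention —
removes that nuisance factor before any group comparison or model input.

A normalized volume of shape ``(nx, ny, nz)`` is then decomposed into
``nx + ny + nz`` 2-D planes: all sagittal slices (fixed x) in ascending
index order, then all coronal (fixed y), then all axial (fixed z).  For an
MNI-grid volume (91 x 109 x 91) this yields the 291 planes consumed by the
slice-submodule classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .images import AtlasVolume, MetabolismVolume

__all__ = [
    "SliceStack",
    "normalize_by_reference",
    "extract_slices",
    "restack",
    "ReferenceRegionNormalizer",
]

AXES = ("sagittal", "coronal", "axial")


@dataclass
class SliceStack:
    """Ordered 2-D planes of one volume along the three orthogonal axes.

    ``slices[i]`` is tagged by ``axes[i] = (axis_name, index)``. Ordering is
    deterministic: sagittal ascending, then coronal, then axial.
    """

    slices: list[np.ndarray]
    axes: list[tuple[str, int]]
    counts: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.slices)


def _reference_mean(data: np.ndarray, atlas: AtlasVolume, reference_name: str) -> float:
    if data.shape != atlas.dims:
        raise ValueError(
            f"volume dims {data.shape} do not match atlas dims {atlas.dims}"
        )
    mask = atlas.mask(reference_name)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"reference region {reference_name!r} is empty")
    ref_mean = float(data[mask].mean())
    if ref_mean <= 0:
        raise ValueError(
            f"reference region {reference_name!r} has non-positive mean "
            f"({ref_mean:g}); cannot normalize"
        )
    return ref_mean


def normalize_by_reference(
    volume: MetabolismVolume,
    atlas: AtlasVolume,
    reference_name: str = "pons",
) -> MetabolismVolume:
    """Divide every voxel by the mean intensity over the reference region.

    The output's reference-region mean is exactly 1 (up to floating point),
    which makes the operation idempotent and invariant to any positive
    global rescaling of the input.
    """
    ref_mean = _reference_mean(volume.data, atlas, reference_name)
    return MetabolismVolume(
        data=volume.data / ref_mean,
        affine=volume.affine,
        subject_id=volume.subject_id,
    )


def extract_slices(volume: MetabolismVolume) -> SliceStack:
    """Decompose a volume into its full set of orthogonal 2-D planes."""
    data = volume.data
    nx, ny, nz = data.shape
    slices: list[np.ndarray] = []
    axes: list[tuple[str, int]] = []
    for i in range(nx):
        slices.append(data[i, :, :])
        axes.append(("sagittal", i))
    for j in range(ny):
        slices.append(data[:, j, :])
        axes.append(("coronal", j))
    for k in range(nz):
        slices.append(data[:, :, k])
        axes.append(("axial", k))
    return SliceStack(slices=slices, axes=axes, counts=(nx, ny, nz))


def restack(stack: SliceStack, axis: str = "sagittal") -> np.ndarray:
    """Reassemble the volume from the planes of one axis (decomposition inverse)."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    planes = [s for s, (a, _) in zip(stack.slices, stack.axes) if a == axis]
    arr = np.stack(planes, axis=0)
    if axis == "sagittal":
        return arr
    if axis == "coronal":
        return arr.transpose(1, 0, 2)
    return arr.transpose(1, 2, 0)


class ReferenceRegionNormalizer(BaseEstimator, TransformerMixin):
    """Transformer applying reference-region normalization volume-by-volume.

    Operates on a stacked array of shape ``(n_subjects, nx, ny, nz)``; each
    subject is divided by the mean of their own reference-region voxels, so
    the transform is stateless (``fit`` only validates the atlas).
    """

    def __init__(self, atlas: AtlasVolume | None = None, reference_name: str = "pons"):
        self.atlas = atlas
        self.reference_name = reference_name

    def fit(self, X, y=None):
        if self.atlas is None:
            raise ValueError("ReferenceRegionNormalizer requires an atlas")
        self.atlas.id_of(self.reference_name)  # raises if absent
        self.reference_mask_ = self.atlas.mask(self.reference_name)
        if not self.reference_mask_.any():
            raise ValueError(f"reference region {self.reference_name!r} is empty")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("expected stacked volumes of shape (n, nx, ny, nz)")
        if X.shape[1:] != self.atlas.dims:
            raise ValueError(
                f"volume dims {X.shape[1:]} do not match atlas dims {self.atlas.dims}"
            )
        means = X[:, self.reference_mask_].mean(axis=1)
        if np.any(means <= 0):
            bad = int(np.argmax(means <= 0))
            raise ValueError(
                f"subject index {bad}: non-positive reference mean {means[bad]:g}"
            )
        return X / means[:, None, None, None]
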