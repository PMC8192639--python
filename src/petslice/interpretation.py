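"""Submodule-significance interpretation of the slice-based classifier.

Class-activation mapping does not apply to an architecture whose spatial
information is collapsed into one scalar per slice before fusion, so the
model's decision basis is approximated from the per-submodule probabilities
instead:

1. Subjects are grouped by the *model's* final classification (not the
   ground truth).  For every submodule, a two-sample t-test (two-tailed,
   alpha = 0.05 by default) compares its probabilities between the two
   predicted groups; slice indices with p < alpha are collected per axis.
2. The three significant-slice sets are combined into the Cartesian point
   cloud {(x, y, z) : x in sig_x, y in sig_y, z in sig_z}.  By
   construction this includes many points unrelated to any true signal —
   only the slice marginals are tested, not the joint locations.
3. To suppress those unrelated points, points are tallied per atlas region
   and only regions holding strictly more than ``min_points`` points are
   reported (50 on an MNI-sized grid, scaled down for toy volumes).

No multiple-testing correction is applied across the per-slice tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import label as cc_label

from .images import AtlasVolume
from .model import PredictionRecord

__all__ = [
    "SignificanceResult",
    "submodule_significance",
    "cartesian_points",
    "extract_roi_clusters",
    "interpret_predictions",
]


@dataclass
class SignificanceResult:
    """Per-axis significant slices, their Cartesian points, surviving ROIs."""

    sig_x: list[int]
    sig_y: list[int]
    sig_z: list[int]
    alpha: float
    points: np.ndarray  # (n_points, 3) voxel coordinates
    roi_point_counts: dict[str, int] = field(default_factory=dict)
    background_points: int = 0
    surviving_rois: list[tuple[str, int]] = field(default_factory=list)


def submodule_significance(
    records: list[PredictionRecord],
    slice_counts: tuple[int, int, int],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> tuple[list[int], list[int], list[int]]:
    """Significant slice indices per axis from per-submodule probabilities.

    Welch's unequal-variance t-test by default (``equal_var=True`` for the
    classical pooled test).  Submodules with zero variance in both predicted
    groups are excluded rather than reported significant.
    """
    if len(records) == 0:
        raise ValueError("no prediction records")
    P = np.vstack([r.submodule_probabilities for r in records])
    g = np.array([r.predicted_class for r in records])
    n_total = sum(slice_counts)
    if P.shape[1] != n_total:
        raise ValueError(
            f"records carry {P.shape[1]} submodule probabilities but "
            f"slice_counts sum to {n_total}"
        )
    for cls in (0, 1):
        if (g == cls).sum() < 2:
            raise ValueError(
                f"predicted class {cls} has fewer than 2 subjects; "
                "cannot run two-sample t-tests"
            )
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant submodule outputs are excluded below, not "significant";
        # silence the precision warning they trigger inside the t-test
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(P[g == 1], P[g == 0], axis=0, equal_var=equal_var)
        pvals = np.asarray(res.pvalue)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance guard
    sig = np.flatnonzero(pvals < alpha)
    nx, ny, nz = slice_counts
    sig_x = [int(i) for i in sig[sig < nx]]
    sig_y = [int(i - nx) for i in sig[(sig >= nx) & (sig < nx + ny)]]
    sig_z = [int(i - nx - ny) for i in sig[sig >= nx + ny]]
    return sig_x, sig_y, sig_z


def cartesian_points(
    sig_x: list[int] | set[int],
    sig_y: list[int] | set[int],
    sig_z: list[int] | set[int],
) -> np.ndarray:
    """All (x, y, z) combinations of the three significant-slice sets.

    The cardinality is |sig_x| * |sig_y| * |sig_z|; empty sets yield an
    empty point cloud.
    """
    xs = np.sort(np.asarray(list(sig_x), dtype=np.int64))
    ys = np.sort(np.asarray(list(sig_y), dtype=np.int64))
    zs = np.sort(np.asarray(list(sig_z), dtype=np.int64))
    if min(len(xs), len(ys), len(zs)) == 0:
        return np.empty((0, 3), dtype=np.int64)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def extract_roi_clusters(
    points: np.ndarray,
    atlas: AtlasVolume,
    min_points: int = 50,
    mode: str = "roi",
) -> tuple[list[tuple[str, int]], dict[str, int], int]:
    """Count points per atlas region and keep regions with count > min_points.

    ``mode="roi"`` (default) tallies points by region label.  The
    alternative ``mode="connected"`` forms connected components of the
    point cloud itself (6-connectivity) and keeps components larger than
    ``min_points``, reporting each by its dominant region.

    Returns ``(surviving, counts, background_count)`` with ``surviving``
    sorted by count descending.
    """
    points = np.asarray(points, dtype=np.int64).reshape(-1, 3)
    dims = atlas.dims
    if len(points):
        if points.min() < 0 or np.any(points >= np.array(dims)):
            bad = points[(points < 0).any(axis=1) | (points >= np.array(dims)).any(axis=1)][0]
            raise ValueError(f"point {tuple(bad)} outside atlas bounds {dims}")
    if mode not in ("roi", "connected"):
        raise ValueError(f"unknown mode {mode!r}")

    labels_at = atlas.labels[points[:, 0], points[:, 1], points[:, 2]] if len(points) else np.array([], dtype=int)
    background = int((labels_at == 0).sum())
    counts: dict[str, int] = {}
    for rid in atlas.region_ids:
        c = int((labels_at == rid).sum())
        if c:
            counts[atlas.name_of(int(rid))] = c

    if mode == "roi":
        surviving = sorted(
            ((name, c) for name, c in counts.items() if c > min_points),
            key=lambda t: (-t[1], t[0]),
        )
        return surviving, counts, background

    # connected-component alternative on the point cloud itself
    grid = np.zeros(dims, dtype=bool)
    if len(points):
        grid[points[:, 0], points[:, 1], points[:, 2]] = True
    comp, n_comp = cc_label(grid)
    surviving = []
    for ci in range(1, n_comp + 1):
        m = comp == ci
        size = int(m.sum())
        if size > min_points:
            region_labels = atlas.labels[m]
            region_labels = region_labels[region_labels > 0]
            if len(region_labels):
                dominant = atlas.name_of(int(np.bincount(region_labels).argmax()))
            else:
                dominant = "background"
            surviving.append((dominant, size))
    surviving.sort(key=lambda t: (-t[1], t[0]))
    return surviving, counts, background


def interpret_predictions(
    records: list[PredictionRecord],
    atlas: AtlasVolume,
    slice_counts: tuple[int, int, int] | None = None,
    alpha: float = 0.05,
    min_points: int = 50,
    equal_var: bool = False,
    mode: str = "roi",
) -> SignificanceResult:
    """Full interpretation pass: t-tests -> point cloud -> surviving ROIs."""
    if slice_counts is None:
        slice_counts = atlas.dims
    sig_x, sig_y, sig_z = submodule_significance(records, slice_counts, alpha, equal_var)
    points = cartesian_points(sig_x, sig_y, sig_z)
    surviving, counts, background = extract_roi_clusters(points, atlas, min_points, mode)
    return SignificanceResult(
        sig_x=sig_x,
        sig_y=sig_y,
        sig_z=sig_z,
        alpha=alpha,
        points=points,
        roi_point_counts=counts,
        background_points=background,
        surviving_rois=surviving,
    )
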