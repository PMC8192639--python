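"""Voxel-wise two-sample t-maps with cluster-extent thresholding.

The classical mass-univariate comparison surface: at every voxel inside an
analysis mask, a two-sample t-test (pooled variance by default, matching
the usual two-sample SPM design; Welch optional) compares the positive and
negative groups.  The map is thresholded at an uncorrected p-value, a
Bonferroni familywise bound, or a permutation max-T familywise correction
(exact at desk scale; parametric random-field correction is not
implemented).  Suprathreshold voxels are split by t sign, grouped into
connected components (18-connectivity by default; 6 and 26 available) and
components of size <= k voxels are discarded — survival requires strictly
more than k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import stats
from scipy.ndimage import generate_binary_structure, label as cc_label
from sklearn.base import BaseEstimator

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterResult",
    "voxelwise_ttest",
    "threshold_and_cluster",
    "VoxelwiseTTest",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Voxel-wise t and two-tailed p maps over an analysis mask."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: float
    mask: np.ndarray
    n_zero_variance: int = 0
    p_fwe_map: np.ndarray | None = None  # permutation max-T corrected p


@dataclass
class Cluster:
    voxels: np.ndarray  # (size, 3) voxel indices
    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    sign: int  # +1 / -1


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    threshold_spec: tuple[float, str, int] = (0.001, "none", 50)

    @property
    def total_voxels(self) -> int:
        return sum(c.size for c in self.clusters)


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized two-sample t over columns; returns (t, p_twotailed, df)."""
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return t, p, df
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df_vec = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * stats.t.sf(np.abs(t), df_vec)
    return t, p, float(np.nanmean(df_vec))


def voxelwise_ttest(
    volumes: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    equal_var: bool = True,
    fwe_permutations: int = 0,
    seed: int | None = None,
) -> StatMap:
    """Two-sample t-test at every masked voxel (positive minus negative group).

    Parameters
    ----------
    volumes : ndarray (n_subjects, nx, ny, nz)
    labels : binary per-subject group membership (1 = amyloid-positive)
    mask : optional boolean volume; defaults to all voxels.  Voxels with
        zero variance within either group are excluded (count logged).
    equal_var : pooled-variance t (default) or Welch.
    fwe_permutations : if > 0, also compute permutation max-T familywise
        corrected p-values with this many label permutations.
    """
    X = np.asarray(volumes, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if X.ndim != 4:
        raise ValueError("volumes must be stacked as (n, nx, ny, nz)")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 subjects per class, got {n_pos} positive / {n_neg} negative"
        )
    dims = X.shape[1:]
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    mask = mask.astype(bool).copy()

    flat = X[:, mask]  # (n, m)
    a, b = flat[y == 1], flat[y == 0]
    nonzero = (a.var(axis=0) > 0) & (b.var(axis=0) > 0)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("excluding %d zero-variance voxels from the mask", n_dropped)
        idx = np.flatnonzero(mask.ravel())[~nonzero]
        mask.ravel()[idx] = False
        flat = X[:, mask]
        a, b = flat[y == 1], flat[y == 0]

    t, p, df = _two_sample_t(a, b, equal_var)
    t_map = np.full(dims, np.nan)
    p_map = np.full(dims, np.nan)
    t_map[mask] = t
    p_map[mask] = p

    p_fwe_map = None
    if fwe_permutations > 0:
        rng = np.random.default_rng(seed)
        max_t = np.empty(fwe_permutations)
        for i in range(fwe_permutations):
            yp = rng.permutation(y)
            tp, _, _ = _two_sample_t(flat[yp == 1], flat[yp == 0], equal_var)
            max_t[i] = np.nanmax(np.abs(tp))
        # corrected p = fraction of permutation maxima >= observed |t|
        p_fwe = (1 + (max_t[None, :] >= np.abs(t)[:, None]).sum(axis=1)) / (
            fwe_permutations + 1
        )
        p_fwe_map = np.full(dims, np.nan)
        p_fwe_map[mask] = p_fwe

    return StatMap(
        t_map=t_map, p_map=p_map, df=df, mask=mask,
        n_zero_variance=n_dropped, p_fwe_map=p_fwe_map,
    )


def threshold_and_cluster(
    stat_map: StatMap,
    p_threshold: float = 0.001,
    correction: str = "none",
    k: int = 50,
    connectivity: int = 18,
) -> ClusterResult:
    """Threshold a t-map and keep connected components of size > k.

    ``correction`` is one of ``"none"`` (uncorrected p), ``"bonferroni"``
    (p multiplied by the number of masked voxels), or ``"fwe_perm"``
    (requires the stat map to carry permutation-corrected p-values).
    Components are formed separately within positive-t and negative-t
    voxels; survival is strict (size ``> k``).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    if correction == "none":
        p = stat_map.p_map
    elif correction == "bonferroni":
        m = int(stat_map.mask.sum())
        p = np.minimum(stat_map.p_map * m, 1.0)
    elif correction == "fwe_perm":
        if stat_map.p_fwe_map is None:
            raise ValueError(
                "stat map has no permutation-corrected p-values; rerun "
                "voxelwise_ttest with fwe_permutations > 0"
            )
        p = stat_map.p_fwe_map
    else:
        raise ValueError(f"unknown correction {correction!r}")

    supra = stat_map.mask & (p < p_threshold)
    structure = generate_binary_structure(3, _CONNECTIVITY[connectivity])
    clusters: list[Cluster] = []
    for sign in (1, -1):
        part = supra & ((stat_map.t_map > 0) if sign == 1 else (stat_map.t_map < 0))
        comp, n_comp = cc_label(part, structure=structure)
        for ci in range(1, n_comp + 1):
            vox = np.argwhere(comp == ci)
            size = len(vox)
            if size <= k:
                continue
            tvals = stat_map.t_map[vox[:, 0], vox[:, 1], vox[:, 2]]
            peak = int(np.argmax(np.abs(tvals)))
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=size,
                    peak_t=float(tvals[peak]),
                    peak_voxel=tuple(int(v) for v in vox[peak]),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(clusters=clusters, threshold_spec=(p_threshold, correction, k))


class VoxelwiseTTest(BaseEstimator):
    """Estimator wrapper: ``fit(X, y)`` computes the group-difference maps.

    Fitted attributes: ``t_map_``, ``p_map_``, ``df_``, ``mask_``,
    ``stat_map_``.
    """

    def __init__(self, mask=None, equal_var=True, fwe_permutations=0, random_state=None):
        self.mask = mask
        self.equal_var = equal_var
        self.fwe_permutations = fwe_permutations
        self.random_state = random_state

    def fit(self, X, y):
        sm = voxelwise_ttest(
            X, y, mask=self.mask, equal_var=self.equal_var,
            fwe_permutations=self.fwe_permutations, seed=self.random_state,
        )
        self.stat_map_ = sm
        self.t_map_ = sm.t_map
        self.p_map_ = sm.p_map
        self.df_ = sm.df
        self.mask_ = sm.mask
        return self

    def clusters(self, p_threshold=0.001, correction="none", k=50, connectivity=18):
        return threshold_and_cluster(
            self.stat_map_, p_threshold, correction, k, connectivity
        )
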