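"""Synthetic FDG-like cohorts and toy atlases.

The generator emulates the statistical structure the downstream analyses
assume about a template-space PET cohort, without any claim to anatomical
realism: an integer-labelled parcellation of contiguous box-shaped regions
(plus dedicated pons and cerebellum reference regions), per-region baseline
intensities, a subject-level global scale factor (the nuisance that
reference-region normalization removes), class-dependent regional effects
(amyloid-positive subjects hypometabolic in a default-mode-like region set
and hypermetabolic in a sensorimotor-like set), additive voxel noise, and
optional Gaussian smoothing.

A companion generator produces amyloid-tracer-like volumes in which target
ROI uptake relative to the cerebellum is drawn above or below a positivity
threshold with a configurable margin, for exercising the SUVR labelling
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import AtlasVolume, MetabolismVolume

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_toy_atlas",
    "generate_cohort",
    "generate_amyloid_cohort",
]

#: FWHM of a Gaussian is 2*sqrt(2*ln 2) times its standard deviation.
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

SUBGROUPS = ("CU", "MCI", "dementia")


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    dims : (nx, ny, nz)
        Voxel grid; must match the paired atlas.
    n_subjects : int
    prevalence : float
        Fraction of amyloid-positive subjects in [0, 1].
    hypo_regions, hyper_regions : list of int
        Atlas region ids with a class-dependent intensity decrease /
        increase in positives.  Must be disjoint.
    effect_size : float
        Fractional intensity change (0.10 = 10 %).
    noise_sd : float
        Voxel noise standard deviation relative to the unit baseline.
    smooth_fwhm_vox : float
        Gaussian smoothing FWHM in voxels (0 disables).
    global_scale_sigma : float
        Log-SD of the subject-level lognormal global scale factor.
    exact_prevalence : bool
        If True (default), realize exactly ``round(prevalence * n)``
        positives; otherwise draw labels i.i.d. Bernoulli(prevalence).
    subgroup_props : dict
        Diagnosis-tag proportions, independent of amyloid label.
    """

    dims: tuple[int, int, int]
    n_subjects: int
    prevalence: float = 0.5
    hypo_regions: list[int] = field(default_factory=list)
    hyper_regions: list[int] = field(default_factory=list)
    effect_size: float = 0.15
    noise_sd: float = 0.05
    smooth_fwhm_vox: float = 2.0
    global_scale_sigma: float = 0.15
    exact_prevalence: bool = True
    subgroup_props: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.4, "MCI": 0.4, "dementia": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        overlap = set(self.hypo_regions) & set(self.hyper_regions)
        if overlap:
            raise ValueError(f"hypo and hyper region sets overlap: {sorted(overlap)}")
        if abs(sum(self.subgroup_props.values()) - 1.0) > 1e-9:
            raise ValueError("subgroup proportions must sum to 1")

    def validate_against(self, atlas: AtlasVolume) -> None:
        if tuple(self.dims) != atlas.dims:
            raise ValueError(f"config dims {self.dims} != atlas dims {atlas.dims}")
        known = set(int(i) for i in atlas.region_ids)
        unknown = (set(self.hypo_regions) | set(self.hyper_regions)) - known
        if unknown:
            raise ValueError(f"region ids not in atlas: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """Generated volumes with their ground-truth labels and diagnosis tags."""

    volumes: list[MetabolismVolume]
    labels: np.ndarray
    subgroups: np.ndarray
    atlas: AtlasVolume

    def __post_init__(self) -> None:
        if not (len(self.volumes) == len(self.labels) == len(self.subgroups)):
            raise ValueError("volumes, labels and subgroups must have equal length")

    def stack(self) -> np.ndarray:
        """All volumes as one array of shape (n_subjects, nx, ny, nz)."""
        return np.stack([v.data for v in self.volumes], axis=0)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [v.subject_id for v in self.volumes],
                "label": self.labels.astype(int),
                "subgroup": self.subgroups,
            }
        )


def generate_toy_atlas(
    dims: tuple[int, int, int],
    n_cortical_regions: int,
    seed: int = 0,
    min_region_voxels: int = 60,
) -> AtlasVolume:
    """Build a box-parcellation atlas with pons and cerebellum references.

    The volume is tiled with cubic boxes on a regular grid; a seeded random
    subset of boxes becomes the ``n_cortical_regions`` cortical regions plus
    the two reference regions.  Every labelled region is a contiguous box of
    at least ``min_region_voxels`` voxels.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 8 for d in dims):
        raise ValueError(f"all dims must be >= 8, got {dims}")
    if n_cortical_regions < 2:
        raise ValueError("need at least 2 cortical regions")
    n_needed = n_cortical_regions + 2  # + pons + cerebellum

    # Largest cubic box edge (>= 4 so each box holds >= 64 voxels) whose
    # grid still provides enough boxes.
    edge = None
    for b in (8, 7, 6, 5, 4):
        if b**3 < min_region_voxels:
            continue
        grid = tuple(d // b for d in dims)
        if int(np.prod(grid)) >= n_needed:
            edge = b
            break
    if edge is None:
        grid4 = tuple(d // 4 for d in dims)
        raise ValueError(
            f"dims {dims} fit only {int(np.prod(grid4))} regions of >= "
            f"{min_region_voxels} voxels; {n_needed} requested "
            f"({n_cortical_regions} cortical + 2 reference)"
        )

    gx, gy, gz = (d // edge for d in dims)
    boxes = [(i, j, k) for i in range(gx) for j in range(gy) for k in range(gz)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(boxes))

    labels = np.zeros(dims, dtype=np.int32)
    names: list[str] = []
    for r in range(n_needed):
        i, j, k = boxes[order[r]]
        sl = (
            slice(i * edge, (i + 1) * edge),
            slice(j * edge, (j + 1) * edge),
            slice(k * edge, (k + 1) * edge),
        )
        labels[sl] = r + 1
        if r < n_cortical_regions:
            names.append(f"region_{r + 1:02d}")
        elif r == n_cortical_regions:
            names.append("pons")
        else:
            names.append("cerebellum")

    regions = pd.DataFrame(
        {
            "id": np.arange(1, n_needed + 1, dtype=np.int32),
            "name": names,
            "is_reference": [n in ("pons", "cerebellum") for n in names],
        }
    )
    return AtlasVolume(labels=labels, regions=regions)


def _draw_labels(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_subjects
    if config.exact_prevalence:
        n_pos = int(round(config.prevalence * n))
        if n_pos == 0 or n_pos == n:
            raise ValueError(
                f"prevalence {config.prevalence} with n={n} leaves zero "
                "subjects in one class (exact-count mode)"
            )
        labels = np.zeros(n, dtype=np.int64)
        labels[rng.permutation(n)[:n_pos]] = 1
    else:
        labels = (rng.random(n) < config.prevalence).astype(np.int64)
    return labels


def _draw_subgroups(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    tags = list(config.subgroup_props.keys())
    probs = np.array([config.subgroup_props[t] for t in tags], dtype=float)
    return rng.choice(np.array(tags, dtype=object), size=config.n_subjects, p=probs).astype(str)


def _region_baseline_map(
    atlas: AtlasVolume, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, float]]:
    # Per-region constants drawn once from [0.8, 1.2) of unit intensity.
    baselines = {
        int(rid): float(rng.uniform(0.8, 1.2)) for rid in np.sort(atlas.region_ids)
    }
    base = np.zeros(atlas.dims, dtype=np.float64)
    for rid, val in baselines.items():
        base[atlas.labels == rid] = val
    return base, baselines


def generate_cohort(config: SyntheticCohortConfig, atlas: AtlasVolume) -> SyntheticCohort:
    """Generate an FDG-like cohort with class-dependent regional effects.

    Each subject's volume is ``global_scale * effect_map + noise`` followed
    by optional Gaussian smoothing, where the effect map multiplies the
    hypo (hyper) regions of positives by ``1 - effect_size``
    (``1 + effect_size``).  The reference regions carry the subject's global
    scale unmodified, so pons normalization is meaningful and removes it.
    Deterministic for a fixed config seed.
    """
    config.validate_against(atlas)
    rng = np.random.default_rng(config.seed)
    base, _ = _region_baseline_map(atlas, rng)
    labels = _draw_labels(config, rng)
    subgroups = _draw_subgroups(config, rng)

    hypo = np.isin(atlas.labels, np.asarray(config.hypo_regions, dtype=np.int64))
    hyper = np.isin(atlas.labels, np.asarray(config.hyper_regions, dtype=np.int64))
    sigma = config.smooth_fwhm_vox * FWHM_TO_SIGMA

    volumes: list[MetabolismVolume] = []
    for i in range(config.n_subjects):
        gscale = float(rng.lognormal(mean=0.0, sigma=config.global_scale_sigma))
        vol = base.copy()
        if labels[i] == 1:
            vol[hypo] *= 1.0 - config.effect_size
            vol[hyper] *= 1.0 + config.effect_size
        vol *= gscale
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd * gscale, size=config.dims)
        if sigma > 0:
            vol = gaussian_filter(vol, sigma=sigma)
        volumes.append(
            MetabolismVolume(data=vol, affine=atlas.affine, subject_id=f"sub-{i:04d}")
        )
    return SyntheticCohort(volumes=volumes, labels=labels, subgroups=subgroups, atlas=atlas)


def generate_amyloid_cohort(
    config: SyntheticCohortConfig,
    atlas: AtlasVolume,
    threshold: float = 1.4,
    margin: float = 0.2,
    target_regions: list[int] | None = None,
    spread: float = 0.3,
) -> SyntheticCohort:
    """Generate amyloid-tracer-like volumes for exercising the SUVR rules.

    Target-ROI uptake relative to the cerebellum is drawn uniformly in
    ``(threshold + margin, threshold + margin + spread)`` for positives and
    ``(threshold - margin - spread, threshold - margin)`` for negatives,
    per ROI.  With ``margin > 0`` the any-of-ROIs rule at ``threshold``
    recovers the generating labels exactly; with ``margin = 0`` draws touch
    the boundary and noise can flip subjects near it.  Smoothing is not
    applied (it would couple ROI means to the background and distort the
    constructed ratios).
    """
    config.validate_against(atlas)
    rng = np.random.default_rng(config.seed)
    if target_regions is None:
        cortical = atlas.regions.loc[~atlas.regions["is_reference"], "id"]
        target_regions = [int(i) for i in cortical.iloc[:4]]
    if len(target_regions) == 0:
        raise ValueError("need at least one target region")

    labels = _draw_labels(config, rng)
    subgroups = _draw_subgroups(config, rng)
    lo_floor = 0.1
    cereb = atlas.mask("cerebellum")
    target_masks = {rid: atlas.labels == rid for rid in target_regions}
    other = atlas.brain_mask() & ~cereb
    for m in target_masks.values():
        other &= ~m

    volumes: list[MetabolismVolume] = []
    for i in range(config.n_subjects):
        gscale = float(rng.lognormal(mean=0.0, sigma=config.global_scale_sigma))
        vol = np.zeros(config.dims, dtype=np.float64)
        vol[cereb] = 1.0
        vol[other] = 1.0
        for m in target_masks.values():
            if labels[i] == 1:
                suvr = threshold + margin + rng.uniform(0.0, spread)
            else:
                suvr = max(threshold - margin - rng.uniform(0.0, spread), lo_floor)
            vol[m] = suvr
        vol *= gscale
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd * gscale, size=config.dims)
        volumes.append(
            MetabolismVolume(data=vol, affine=atlas.affine, subject_id=f"sub-{i:04d}")
        )
    return SyntheticCohort(volumes=volumes, labels=labels, subgroups=subgroups, atlas=atlas)
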