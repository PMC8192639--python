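"""ROI SUVR quantification and tracer-specific amyloid-positivity rules.

The standardized uptake value ratio (SUVR) of a region of interest is the
mean tracer uptake over the ROI's voxels divided by the mean uptake of a
reference region — here the cerebellum, chosen for its low amyloid
deposition.  Ground-truth positivity is decided per tracer:

* florbetapir: composite (global) SUVR over the union of target ROIs,
  positive when strictly greater than 1.11;
* PiB: positive when SUVR > 1.4 in at least one of four target ROIs;
* florbetaben: positive when SUVR > 1.478 in at least one of four ROIs.

All comparisons are strict: a SUVR exactly at the threshold is negative.
The target-ROI composition is atlas configuration, not code — real
parcellations differ between datasets, and toy atlases use any four
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import AtlasVolume, MetabolismVolume

__all__ = [
    "SUVRResult",
    "PositivityRule",
    "compute_roi_suvr",
    "compute_composite_suvr",
    "classify_positivity",
    "label_cohort",
    "florbetapir_rule",
    "pib_rule",
    "florbetaben_rule",
]

COMPOSITE = "composite"


@dataclass
class SUVRResult:
    """Per-ROI SUVRs for one subject."""

    roi_suvrs: dict[str, float]
    reference_name: str
    tracer: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name, v in self.roi_suvrs.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SUVR for {name!r} must be positive and finite, got {v}")


@dataclass
class PositivityRule:
    """One tracer's decision rule.

    ``mode="global"`` compares a single composite SUVR (stored under the
    ``"composite"`` key) against the threshold; ``mode="any_of_rois"``
    declares positivity when any listed ROI exceeds it.  Comparison is
    strict (``>``).
    """

    tracer: str
    mode: str
    threshold: float
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.mode not in ("global", "any_of_rois"):
            raise ValueError(f"unknown mode {self.mode!r}")


def florbetapir_rule(roi_names: list[str] | None = None) -> PositivityRule:
    """Global composite SUVR > 1.11."""
    return PositivityRule("florbetapir", "global", 1.11, roi_names or [])


def pib_rule(roi_names: list[str] | None = None) -> PositivityRule:
    """Any of the four target ROIs with SUVR > 1.4."""
    return PositivityRule("pib", "any_of_rois", 1.4, roi_names or [])


def florbetaben_rule(roi_names: list[str] | None = None) -> PositivityRule:
    """Any of the four target ROIs with SUVR > 1.478."""
    return PositivityRule("florbetaben", "any_of_rois", 1.478, roi_names or [])


def _masked_mean(data: np.ndarray, mask: np.ndarray, what: str) -> float:
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"{what} is empty")
    return float(data[mask].mean())


def compute_roi_suvr(
    volume: MetabolismVolume,
    atlas: AtlasVolume,
    roi_names: list[str],
    reference_name: str = "cerebellum",
    tracer: str = "",
) -> SUVRResult:
    """SUVR per ROI: mean(ROI voxels) / mean(reference voxels)."""
    if volume.dims != atlas.dims:
        raise ValueError(f"volume dims {volume.dims} != atlas dims {atlas.dims}")
    ref_mean = _masked_mean(volume.data, atlas.mask(reference_name), f"reference {reference_name!r}")
    if ref_mean <= 0:
        raise ValueError(f"reference {reference_name!r} has non-positive mean {ref_mean:g}")
    suvrs = {
        name: _masked_mean(volume.data, atlas.mask(name), f"ROI {name!r}") / ref_mean
        for name in roi_names
    }
    return SUVRResult(
        roi_suvrs=suvrs,
        reference_name=reference_name,
        tracer=tracer,
        subject_id=volume.subject_id,
    )


def compute_composite_suvr(
    volume: MetabolismVolume,
    atlas: AtlasVolume,
    roi_names: list[str],
    reference_name: str = "cerebellum",
    tracer: str = "",
) -> SUVRResult:
    """Composite SUVR: voxel mean over the *union* of target ROIs vs reference."""
    if volume.dims != atlas.dims:
        raise ValueError(f"volume dims {volume.dims} != atlas dims {atlas.dims}")
    if not roi_names:
        raise ValueError("composite SUVR needs at least one ROI")
    union = np.zeros(atlas.dims, dtype=bool)
    for name in roi_names:
        union |= atlas.mask(name)
    ref_mean = _masked_mean(volume.data, atlas.mask(reference_name), f"reference {reference_name!r}")
    if ref_mean <= 0:
        raise ValueError(f"reference {reference_name!r} has non-positive mean {ref_mean:g}")
    comp = _masked_mean(volume.data, union, "composite ROI union") / ref_mean
    return SUVRResult(
        roi_suvrs={COMPOSITE: comp},
        reference_name=reference_name,
        tracer=tracer,
        subject_id=volume.subject_id,
    )


def classify_positivity(suvr_result: SUVRResult, rule: PositivityRule) -> int:
    """Apply a tracer rule; returns 1 (positive) or 0 (negative)."""
    if rule.mode == "global":
        if COMPOSITE not in suvr_result.roi_suvrs:
            raise ValueError("global rule requires a 'composite' SUVR entry")
        return int(suvr_result.roi_suvrs[COMPOSITE] > rule.threshold)
    missing = [n for n in rule.roi_names if n not in suvr_result.roi_suvrs]
    if missing:
        raise ValueError(f"rule ROIs missing from SUVR result: {missing}")
    if not rule.roi_names:
        raise ValueError("any_of_rois rule has no ROIs")
    max_suvr = max(suvr_result.roi_suvrs[n] for n in rule.roi_names)
    return int(max_suvr > rule.threshold)


def label_cohort(
    volumes: list[MetabolismVolume],
    atlas: AtlasVolume,
    rule: PositivityRule,
    roi_names: list[str] | None = None,
    reference_name: str = "cerebellum",
) -> pd.DataFrame:
    """SUVRs and positivity status for a list of subjects.

    For a global rule the composite SUVR over the union of ``roi_names``
    (defaulting to the rule's ROI list) is used; per-ROI SUVRs are reported
    alongside either way.
    """
    rois = roi_names or rule.roi_names
    rows = []
    for vol in volumes:
        res = compute_roi_suvr(vol, atlas, rois, reference_name, rule.tracer)
        if rule.mode == "global":
            comp = compute_composite_suvr(vol, atlas, rois, reference_name, rule.tracer)
            res.roi_suvrs[COMPOSITE] = comp.roi_suvrs[COMPOSITE]
            status = classify_positivity(comp, rule)
        else:
            status = classify_positivity(res, rule)
        row = {"subject_id": vol.subject_id, "tracer": rule.tracer, "status": status}
        row.update({f"suvr_{k}": v for k, v in res.roi_suvrs.items()})
        rows.append(row)
    return pd.DataFrame(rows)
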