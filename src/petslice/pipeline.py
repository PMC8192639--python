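"""End-to-end workflow: simulate -> normalize -> train -> predict ->
evaluate -> interpret -> voxel-wise, with a reproducibility manifest.

The manifest records the configuration hash, the seed, and a SHA-256
content hash per written artifact, so a run is reproducible from
``(config, seed)`` alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .evaluation import compute_metrics, subgroup_report
from .images import MetabolismVolume
from .interpretation import interpret_predictions
from .model import ModelConfig, SliceSubmoduleClassifier
from .preprocessing import ReferenceRegionNormalizer
from .synthetic import SyntheticCohortConfig, generate_cohort, generate_toy_atlas
from .voxelwise import threshold_and_cluster, voxelwise_ttest

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "train", "predict", "evaluate", "interpret", "voxelwise")


@dataclass
class RunConfig:
    """Configuration for one pipeline run; defaults are desk-scale."""

    out_dir: str = "petslice_run"
    seed: int = 0
    dims: tuple[int, int, int] = (24, 28, 24)
    n_subjects: int = 100
    n_cortical_regions: int = 8
    prevalence: float = 0.5
    hypo_regions: tuple[int, ...] = (1, 2)
    hyper_regions: tuple[int, ...] = (3,)
    effect_size: float = 0.15
    noise_sd: float = 0.05
    smooth_fwhm_vox: float = 2.0
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        conv_filters=(8, 16, 32, 32), max_epochs=8))
    alpha: float = 0.05
    min_points: int = 20
    p_threshold: float = 0.001
    correction: str = "none"
    cluster_k: int = 50
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "model" in raw:
            raw["model"] = ModelConfig(**{
                k: tuple(v) if k == "conv_filters" else v
                for k, v in raw["model"].items()
            })
        for key in ("dims", "hypo_regions", "hyper_regions", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest: dict = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
        for p in paths:
            outputs[p.name] = p

    atlas = cohort = None
    norm = clf = records = None

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        try:
            if stage == "simulate":
                atlas = generate_toy_atlas(config.dims, config.n_cortical_regions,
                                           seed=config.seed)
                cohort_cfg = SyntheticCohortConfig(
                    dims=config.dims, n_subjects=config.n_subjects,
                    prevalence=config.prevalence,
                    hypo_regions=list(config.hypo_regions),
                    hyper_regions=list(config.hyper_regions),
                    effect_size=config.effect_size, noise_sd=config.noise_sd,
                    smooth_fwhm_vox=config.smooth_fwhm_vox, seed=config.seed + 1,
                )
                cohort = generate_cohort(cohort_cfg, atlas)
                pio.write_atlas(atlas, out / "atlas.nii.gz", out / "regions.csv")
                pio.write_labels(cohort.frame(), out / "labels.csv")
                record(stage, out / "atlas.nii.gz", out / "regions.csv",
                       out / "labels.csv")
            elif stage == "train":
                if cohort is None:
                    raise ValueError("train requires the simulate stage")
                norm = ReferenceRegionNormalizer(atlas=atlas).fit(None)
                Xn = norm.transform(cohort.stack())
                clf = config.model.estimator()
                clf.set_params(random_state=config.seed + 2)
                clf.fit(Xn, cohort.labels)
                clf.save(out / "model.npz")
                clf.history_.to_csv(out / "history.csv", index=False)
                record(stage, out / "model.npz", out / "history.csv")
            elif stage == "predict":
                if clf is None:
                    raise ValueError("predict requires the train stage")
                Xn = norm.transform(cohort.stack())
                records = clf.predict_record(
                    Xn, subject_ids=[v.subject_id for v in cohort.volumes])
                import pandas as pd

                df = pd.DataFrame({
                    "subject_id": [r.subject_id for r in records],
                    "final_probability": [r.final_probability for r in records],
                    "predicted_class": [r.predicted_class for r in records],
                })
                df.to_csv(out / "predictions.csv", index=False)
                np.savetxt(out / "submodule_probabilities.csv",
                           np.vstack([r.submodule_probabilities for r in records]),
                           delimiter=",")
                record(stage, out / "predictions.csv",
                       out / "submodule_probabilities.csv")
            elif stage == "evaluate":
                if records is None:
                    raise ValueError("evaluate requires the predict stage")
                proba = np.array([r.final_probability for r in records])
                overall = compute_metrics(cohort.labels, proba,
                                          clf.decision_threshold)
                rows = subgroup_report(cohort.labels, proba, cohort.subgroups,
                                       clf.decision_threshold)
                payload = {
                    "overall": overall.as_dict(),
                    "subgroups": {r.subgroup: r.as_dict() for r in rows},
                }
                (out / "metrics.json").write_text(
                    json.dumps(payload, indent=2, default=float))
                record(stage, out / "metrics.json")
            elif stage == "interpret":
                if records is None:
                    raise ValueError("interpret requires the predict stage")
                res = interpret_predictions(records, atlas,
                                            slice_counts=config.dims,
                                            alpha=config.alpha,
                                            min_points=config.min_points)
                payload = {
                    "alpha": res.alpha,
                    "sig_x": res.sig_x, "sig_y": res.sig_y, "sig_z": res.sig_z,
                    "n_points": int(len(res.points)),
                    "roi_point_counts": res.roi_point_counts,
                    "background_points": res.background_points,
                    "surviving_rois": res.surviving_rois,
                }
                (out / "interpretation.json").write_text(
                    json.dumps(payload, indent=2))
                record(stage, out / "interpretation.json")
            elif stage == "voxelwise":
                if cohort is None:
                    raise ValueError("voxelwise requires the simulate stage")
                Xn = (norm.transform(cohort.stack()) if norm is not None
                      else cohort.stack())
                sm = voxelwise_ttest(Xn, cohort.labels,
                                     mask=atlas.brain_mask())
                cr = threshold_and_cluster(sm, config.p_threshold,
                                           config.correction, config.cluster_k)
                pio.write_volume(
                    MetabolismVolume(np.nan_to_num(sm.t_map), atlas.affine, "tmap"),
                    out / "t_map.nii.gz")
                import pandas as pd

                pd.DataFrame([
                    {"size": c.size, "peak_t": c.peak_t,
                     "peak_voxel": str(c.peak_voxel), "sign": c.sign}
                    for c in cr.clusters
                ]).to_csv(out / "clusters.csv", index=False)
                record(stage, out / "t_map.nii.gz", out / "clusters.csv")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].setdefault(stage, {})
        manifest["stages"][stage]["seconds"] = round(time.time() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
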