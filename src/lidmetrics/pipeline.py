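"""End-to-end pipeline: simulate -> localize -> normalize -> train -> evaluate.

One master seed fans out to independent per-stage seeds through a hash-based
splitter, so rerunning any stage with the same configuration reproduces its
outputs without coupling stages to each other.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eyegen, landmarks, normalize, predictor, evalstats

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed",
           "build_patches"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    n_subjects: int = 50
    seed: int = 0
    dist: eyegen.DistributionConfig = field(default_factory=eyegen.DistributionConfig)
    split_plan: predictor.SplitPlan = field(default_factory=predictor.SplitPlan)
    train_config: predictor.TrainConfig = field(default_factory=predictor.TrainConfig)
    targets: tuple[str, ...] = ("mrd1", "mrd2", "lf")
    # use the manifest's ground-truth reflex coordinates (training workflow);
    # False runs the classical detector instead (found-data workflow)
    ground_truth_reflex: bool = True
    out_dir: str | None = None


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    reports: dict[str, evalstats.AgreementReport]
    predictions: pd.DataFrame
    results: dict[str, predictor.EyelidRegressionResults]
    exclusions: dict[str, int]


def build_patches(dataset: eyegen.SyntheticDataset, *,
                  ground_truth_reflex: bool = True
                  ) -> tuple[dict, dict, dict[str, int]]:
    """Normalized primary patches and merged up/down patches per eye.

    Returns ``(primary, merged, exclusion_counts)``; an eye missing a usable
    reflex coordinate in a gaze drops out of the corresponding patch set
    (the "not well merged" bookkeeping for levator function).
    """
    manifest = dataset.manifest
    primary: dict[str, normalize.NormalizedPatch] = {}
    merged: dict[str, normalize.NormalizedPatch] = {}
    exclusions = {"primary": 0, "merged": 0}

    def _reflex(row):
        if ground_truth_reflex:
            return (row.reflex_x_px, row.reflex_y_px)
        det = landmarks.detect_reflex_classical(dataset.images[_image_id(row)])
        return None if det is None else (det.x, det.y)

    def _image_id(row):
        return f"{row.eye_id}_{row.gaze}"

    for eye_id, group in manifest.groupby("eye_id"):
        rows = {r.gaze: r for r in group.itertuples()}
        crops = {}
        for gaze in ("primary", "up", "down"):
            row = rows.get(gaze)
            if row is None:
                continue
            reflex = _reflex(row)
            if reflex is None:
                continue
            crop, origin = normalize.crop_primary(dataset.images[_image_id(row)], reflex)
            crops[gaze] = (crop, origin)
        if "primary" in crops:
            crop, origin = crops["primary"]
            primary[eye_id] = normalize.resize_patch(
                crop, source_gaze="primary", origin_px=origin, eye_id=eye_id)
        else:
            exclusions["primary"] += 1
        try:
            m = normalize.merge_gazes(
                crops["up"][0] if "up" in crops else None,
                crops["down"][0] if "down" in crops else None)
        except normalize.MergeExclusion:
            exclusions["merged"] += 1
        else:
            merged[eye_id] = normalize.resize_patch(
                m, source_gaze="merged", eye_id=eye_id)
    return primary, merged, exclusions


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; raises with the stage name on failure."""
    stage = "simulate"
    try:
        dataset = eyegen.generate_dataset(
            config.n_subjects, config.dist,
            seed=derive_seed(config.seed, "simulate"), out_dir=config.out_dir)
        log.info("simulate: %d images, %d eyes", len(dataset.manifest),
                 dataset.manifest["eye_id"].nunique())

        stage = "normalize"
        primary, merged, exclusions = build_patches(
            dataset, ground_truth_reflex=config.ground_truth_reflex)
        log.info("normalize: %d primary patches, %d merged patches, "
                 "%d primary / %d merged exclusions",
                 len(primary), len(merged), exclusions["primary"], exclusions["merged"])

        stage = "split"
        manifest = predictor.split_dataset(
            dataset.manifest, config.split_plan, seed=derive_seed(config.seed, "split"))
        counts = manifest.drop_duplicates("eye_id")["partition"].value_counts()
        log.info("split: %s", counts.to_dict())

        reports: dict[str, evalstats.AgreementReport] = {}
        results: dict[str, predictor.EyelidRegressionResults] = {}
        pred_rows = []
        for target in config.targets:
            stage = f"train[{target}]"
            patches = merged if target == "lf" else primary
            cfg_d = dict(config.train_config.__dict__)
            cfg_d["seed"] = derive_seed(config.seed, f"train:{target}")
            cfg = predictor.TrainConfig(**cfg_d)
            model = predictor.EyelidRegression.from_manifest(
                manifest, patches, target=target, config=cfg, partition="trainval")
            results[target] = model.fit()
            log.info("%s: mean fold val MAE %.3f mm", stage,
                     results[target].fold_metrics["val_mae_mm"].mean())

            stage = f"evaluate[{target}]"
            test = manifest[manifest["partition"] == "test"].drop_duplicates("eye_id")
            eye_ids = [e for e in test["eye_id"] if e in patches]
            actual = test.set_index("eye_id").loc[eye_ids, f"{target}_mm"].to_numpy()
            predicted = results[target].predict([patches[e] for e in eye_ids])
            reports[target] = evalstats.build_report(actual, predicted)
            for e, a, p in zip(eye_ids, actual, predicted):
                pred_rows.append({"eye_id": e, "target": target,
                                  "actual_mm": a, "predicted_mm": p})
            log.info("%s: test MAE %.3f mm (n=%d)", stage, reports[target].mae,
                     reports[target].n)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    predictions = pd.DataFrame(pred_rows)
    if config.out_dir is not None:
        from pathlib import Path
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out / "manifest_partitioned.csv", index=False)
        predictions.to_csv(out / "predictions.csv", index=False)
        for target, report in reports.items():
            (out / f"report_{target}.txt").write_text(report.summary() + "\n")
    return PipelineResult(manifest, reports, predictions, results, exclusions)
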