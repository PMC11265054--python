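"""End-to-end orchestration: simulate -> scattergrams -> train -> calibrate -> evaluate.

The pipeline mirrors a two-cohort protocol: a *development* cohort supplies
augmented (9-beat step) training images, the 9:1 image-level split, and the
three threshold calibrations; a separately seeded *evaluation* cohort is
scored with non-overlapping windows only, the deployment setting, and
yields the reported two-level performance.

All randomness funnels through one integer seed; stage seeds are spawned
deterministically from it, so a rerun with the same configuration
reproduces every threshold and metric exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cnn import CNNModel, ModelConfig, TrainingHistory, build_model, predict_proba, train
from .metrics import (RecordAggregation, ThresholdSet, TwoLevelReport,
                      calibrate_thresholds, evaluate_two_level)
from .records import BeatClass, RecordClass, RRRecord, read_rri_text
from .scattergram import (WINDOW_BEATS, LSImage, RasterSpec,
                          record_to_images, split_dataset)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RecordPrediction",
    "run_pipeline",
    "predict_record",
    "calibrate_from_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One document configuring every stage (single global seed)."""

    n_per_class: int = 10
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    raster: RasterSpec = field(default_factory=RasterSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train_fraction: float = 0.9
    augment_training: bool = True
    aggregation: RecordAggregation = RecordAggregation.AF_FRACTION
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "n_per_class": self.n_per_class,
            "simulation": asdict(self.simulation),
            "raster": asdict(self.raster),
            "model": asdict(self.model),
            "train_fraction": self.train_fraction,
            "augment_training": self.augment_training,
            "aggregation": self.aggregation.value,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RecordPrediction:
    """Deployment decision for one record, with audit trail."""

    record_id: str
    decision: RecordClass
    af_burden: float
    window_scores: np.ndarray


@dataclass
class PipelineResult:
    """Everything the pipeline produced, tagged with the config hash."""

    config: PipelineConfig
    config_hash: str
    model: CNNModel
    history: TrainingHistory
    thresholds: ThresholdSet
    report: TwoLevelReport
    validation_auc: Optional[float]
    manifest: list[dict]


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _record_images_nonoverlap(records: Sequence[RRRecord],
                              spec: RasterSpec) -> dict[str, list[LSImage]]:
    return {r.record_id: record_to_images(r, spec, augment=False) for r in records}


def _score_images(model: CNNModel, images: Sequence[LSImage]) -> np.ndarray:
    return predict_proba(model, list(images))


def calibrate_from_cohort(model: CNNModel,
                          calibration_images: Sequence[LSImage],
                          calibration_records: Sequence[RRRecord],
                          spec: Optional[RasterSpec] = None,
                          aggregation: RecordAggregation = RecordAggregation.AF_FRACTION,
                          ) -> ThresholdSet:
    """Calibrate the three cutoffs from a model plus labeled calibration data.

    Image cutoff from the calibration images' ROC; record cutoffs from the
    AF-burden fractions of the calibration records (non-overlapping
    windows), via Youden maximization at each level.
    """
    spec = spec if spec is not None else model.raster_spec
    img_scores = _score_images(model, calibration_images)
    img_labels = [img.label for img in calibration_images]
    per_record = _record_images_nonoverlap(calibration_records, spec)
    rec_scores = {rid: _score_images(model, imgs) for rid, imgs in per_record.items()
                  if imgs}
    rids = list(rec_scores.keys())
    truths = {r.record_id: r.record_truth for r in calibration_records}

    def fractions_at(ls_cutoff: float, _agg=aggregation):
        from .metrics import record_score
        return [record_score(rec_scores[rid], ls_cutoff, _agg) for rid in rids]

    return calibrate_thresholds(img_scores, img_labels, fractions_at,
                                [truths[rid] for rid in rids])


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run every stage and return the report bundle.

    Stages: (1) simulate the development cohort; (2) build augmented
    training images and the 9:1 split; (3) train the CNN for the fixed
    epoch budget; (4) calibrate the three cutoffs on the development
    cohort; (5) simulate a fresh evaluation cohort and produce the
    two-level report on non-overlapping windows.
    """
    t0 = time.time()
    cfg = config
    chash = cfg.config_hash()
    seed_dev, seed_eval, seed_split, seed_model = _stage_seeds(cfg.seed, 4)

    def log(stage: str, msg: str) -> None:
        logger.info("[%s] %s (t=%.1fs, config=%s)", stage, msg, time.time() - t0, chash)

    sim_dev = replace(cfg.simulation, seed=seed_dev)
    dev_records = simulate_cohort(cfg.n_per_class, sim_dev)
    log("simulate", f"development cohort: {len(dev_records)} records")

    train_pool: list[LSImage] = []
    manifest: list[dict] = []
    for rec in dev_records:
        imgs = record_to_images(rec, cfg.raster, augment=cfg.augment_training)
        train_pool.extend(imgs)
        manifest.append({
            "record_id": rec.record_id, "role": "development",
            "truth": rec.record_truth.value if rec.record_truth else None,
            "n_beats": len(rec), "n_windows": len(imgs),
        })
    log("make-ls", f"{len(train_pool)} training-pool images "
                   f"({sum(1 for i in train_pool if i.label is BeatClass.AF)} AF)")

    train_imgs, val_imgs = split_dataset(train_pool, cfg.train_fraction, seed=seed_split)
    model_cfg = replace(cfg.model, seed=seed_model)
    model = build_model(model_cfg, cfg.raster)
    model, history = train(model, train_imgs, val_imgs, model_cfg)
    log("train", f"{model_cfg.epochs} epochs on {len(train_imgs)} images; "
                 f"final val acc {history.val_accuracy[-1]:.3f}")

    # held-out (validation-split) image-level AUC
    from .metrics import auc as _auc, roc_curve as _roc
    val_scores = _score_images(model, val_imgs)
    val_labels = [im.label for im in val_imgs]
    val_y = [lbl is BeatClass.AF for lbl in val_labels]
    validation_auc = _auc(_roc(val_scores, val_y)) if 0 < sum(val_y) < len(val_y) else None

    thresholds = calibrate_from_cohort(model, train_pool, dev_records,
                                       cfg.raster, cfg.aggregation)
    log("calibrate", f"ls={thresholds.ls_cutoff:.3f} "
                     f"af={thresholds.record_af_cutoff:.3f} "
                     f"persistent={thresholds.persistent_cutoff:.3f}")

    sim_eval = replace(cfg.simulation, seed=seed_eval)
    eval_records = simulate_cohort(cfg.n_per_class, sim_eval)
    per_record = _record_images_nonoverlap(eval_records, cfg.raster)
    eval_images = [im for imgs in per_record.values() for im in imgs]
    eval_scores_flat = _score_images(model, eval_images)
    offsets = np.cumsum([0] + [len(imgs) for imgs in per_record.values()])
    rec_scores = {rid: eval_scores_flat[offsets[k]:offsets[k + 1]]
                  for k, rid in enumerate(per_record.keys())}
    truths = {r.record_id: r.record_truth for r in eval_records}
    report = evaluate_two_level(
        eval_scores_flat, [im.label for im in eval_images], thresholds,
        rec_scores, truths, cfg.aggregation)
    for rec in eval_records:
        manifest.append({
            "record_id": rec.record_id, "role": "evaluation",
            "truth": rec.record_truth.value if rec.record_truth else None,
            "n_beats": len(rec), "n_windows": len(per_record[rec.record_id]),
        })
    log("evaluate", f"record accuracy {report.record_accuracy:.3f}, "
                    f"image AUC {report.image_level.auc}")

    return PipelineResult(config=cfg, config_hash=chash, model=model,
                          history=history, thresholds=thresholds, report=report,
                          validation_auc=validation_auc, manifest=manifest)


def predict_record(model: CNNModel, thresholds: ThresholdSet,
                   record: Union[RRRecord, str, Path],
                   spec: Optional[RasterSpec] = None,
                   aggregation: RecordAggregation = RecordAggregation.AF_FRACTION,
                   ) -> RecordPrediction:
    """Classify one record (non-AF / paroxysmal / persistent).

    Accepts an in-memory record or a path to an RRI TSV file.  The record
    is cut into non-overlapping 85-beat windows; fewer than 85 beats is an
    explicit "insufficient beats" error.
    """
    from .metrics import classify_record, record_score
    if not isinstance(record, RRRecord):
        record = read_rri_text(record)
    spec = spec if spec is not None else model.raster_spec
    images = record_to_images(record, spec, augment=False)
    if not images:
        raise ValueError(
            f"insufficient beats: record {record.record_id!r} has {len(record)} "
            f"beats; at least {WINDOW_BEATS} are required for one window"
        )
    scores = _score_images(model, images)
    burden = record_score(scores, thresholds.ls_cutoff, aggregation)
    return RecordPrediction(
        record_id=record.record_id,
        decision=classify_record(burden, thresholds),
        af_burden=burden,
        window_scores=scores,
    )
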