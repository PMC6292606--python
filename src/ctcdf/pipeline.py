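"""End-to-end orchestration: train on a manifest split, detect, evaluate.

The stages mirror the detection workflow: illumination correction, channel
features, boosted pixel classification, morphological post-processing, and
object-level evaluation against the ground-truth masks.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import boosting, evaluation, postprocess
from .boosting import BoostModel, FeatureConfig
from .config import RunConfig
from .image_io import (
    BinaryMask,
    DatasetManifest,
    read_image,
    read_mask,
    write_detections,
)
from .postprocess import DetectedObject

logger = logging.getLogger(__name__)


def _load_pairs(manifest: DatasetManifest):
    pairs = []
    missing = [str(e.image) for e in manifest.entries if e.mask is None]
    if missing:
        raise ValueError(f"manifest entries lack masks: {missing}")
    for e in manifest.entries:
        image = read_image(e.image)
        mask = read_mask(e.mask, image.height, image.width)
        pairs.append((image, mask))
    return pairs


def train_on_manifest(manifest: DatasetManifest, config: RunConfig) -> BoostModel:
    """Sample labeled pixels from every manifest entry and fit the ensemble."""
    feature_config = FeatureConfig(
        pattern=config.pattern(), illumination=config.illumination()
    )
    pairs = _load_pairs(manifest)
    logger.info("sampling training pixels from %d images", len(pairs))
    samples = boosting.sample_training_pixels(
        [p[0] for p in pairs],
        [p[1] for p in pairs],
        feature_config,
        neg_pos_ratio=config.neg_pos_ratio,
        max_pos_per_image=config.max_pos_per_image,
        seed=config.seed,
    )
    logger.info("training %d rounds on %d samples", config.rounds, len(samples))
    return boosting.train_adaboost(
        samples,
        n_rounds=config.rounds,
        seed=config.seed,
        feature_config=feature_config,
        score_threshold=config.score_threshold,
    )


def detect_image(image, model: BoostModel, config: RunConfig) -> list[DetectedObject]:
    """Score, binarize and post-process one frame into validated objects."""
    scores = boosting.predict_scores(image, model, config.illumination())
    pixel_mask = boosting.threshold_scores(scores, model.score_threshold)
    pixel_mask.id = image.id
    return postprocess.detect_objects(
        pixel_mask, opening_radius=config.opening_radius, min_area=config.min_area
    )


def evaluate_manifest(
    manifest: DatasetManifest,
    model: BoostModel,
    config: RunConfig,
    out_dir: str | Path | None = None,
):
    """Detect on every manifest entry and score against its ground truth.

    Returns ``(MetricsReport, per-image counts DataFrame)``; when ``out_dir``
    is given, also writes per-image detection CSVs, the counts table and the
    metrics JSON there.
    """
    pairs = _load_pairs(manifest)
    per_image = {}
    all_detections = []
    for image, gt_mask in pairs:
        detections = detect_image(image, model, config)
        gt_objects = postprocess.label_components(gt_mask)
        per_image[image.id] = (detections, gt_objects)
        all_detections.extend(detections)
        logger.info(
            "image %s: %d detections, %d ground-truth objects",
            image.id,
            len(detections),
            len(gt_objects),
        )
    report, table = evaluation.evaluate_detections(
        per_image,
        overlap_threshold=config.overlap_threshold,
        avg_cells_per_image=config.avg_cells_per_image,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_detections(all_detections, out_dir / "detections.csv")
        table.to_csv(out_dir / "per_image_counts.csv", index=False)
        evaluation.write_metrics(report, out_dir / "metrics.json")
    return report, table


def run_pipeline(
    manifest: DatasetManifest,
    config: RunConfig,
    out_dir: str | Path | None = None,
):
    """Train on the ``train`` split, evaluate on the ``test`` split.

    Returns ``(model, MetricsReport, per-image counts DataFrame)``.
    """
    train_split = manifest.subset("train")
    test_split = manifest.subset("test")
    if not len(train_split) or not len(test_split):
        raise ValueError(
            f"manifest needs both splits; got {len(train_split)} train / "
            f"{len(test_split)} test entries"
        )
    model = train_on_manifest(train_split, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        boosting.save_model(model, out_dir / "model.json")
    report, table = evaluate_manifest(test_split, model, config, out_dir=out_dir)
    return model, report, table
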