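"""Discrete AdaBoost over decision stumps for per-pixel CTC classification.

The classifier labels each pixel of a darkfield frame as tumor-cell (+1) or
not (-1) from its multi-resolution channel feature vector.  The ensemble is
classical discrete AdaBoost with depth-1 stumps:

* sample weights start uniform at 1/n;
* each round picks the (feature, threshold, polarity) stump minimizing the
  weighted 0-1 error over *all* candidate thresholds (midpoints of sorted
  unique feature values — the exact optimal stump, not a subsample);
* ``alpha_t = 0.5 * ln((1 - eps_t) / eps_t)`` with ``eps`` clamped away from
  {0, 1}; weights are multiplied by ``exp(-alpha_t * y * h_t(x))`` and
  renormalized;
* training stops early when no stump beats chance (``eps >= 0.5``) or when a
  stump is already perfect.

The ensemble score of a vector is ``sum_t alpha_t * h_t(x)``; a pixel is
called tumor when the score strictly exceeds ``score_threshold`` (ties go to
non-CTC).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .channels import (
    LEVEL_SCALES,
    CHANNELS_PER_LEVEL,
    ChannelStack,
    NeighborhoodPattern,
    compute_channel_stack,
    extract_feature_matrix,
    feature_dimension,
)
from .illumination import IlluminationConfig, correct_illumination
from .image_io import BinaryMask, RasterImage

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
EPS_CLAMP = 1e-10


@dataclass
class PixelSample:
    """One labeled training pixel: feature vector, label, provenance."""

    features: np.ndarray
    label: int  # +1 tumor-cell pixel, -1 background/blood pixel
    source: tuple[str, int, int] = ("", -1, -1)

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class DecisionStump:
    """One-feature threshold classifier: ``h(x) = polarity * sign(x_f - t)``.

    ``sign`` here maps strictly-greater to +1 and less-or-equal to -1 (no
    sample ever sits on a midpoint threshold during training).
    """

    feature_index: int
    threshold: float
    polarity: int
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = np.where(X[:, self.feature_index] > self.threshold, 1, -1)
        return self.polarity * raw


@dataclass
class FeatureConfig:
    """Everything needed to rebuild the model's input space at predict time."""

    pattern: NeighborhoodPattern
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern.to_dict(),
            "illumination": {"wsize": self.illumination.wsize},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            pattern=NeighborhoodPattern.from_dict(d["pattern"]),
            illumination=IlluminationConfig(wsize=int(d["illumination"]["wsize"])),
        )


@dataclass
class BoostModel:
    stumps: list[DecisionStump]
    feature_config: FeatureConfig
    n_rounds: int
    seed: int
    score_threshold: float = 0.0
    n_features: int | None = None  # width of the training matrix, if known
    train_errors: list[float] = field(default_factory=list, repr=False)

    @property
    def feature_dim(self) -> int:
        if self.n_features is not None:
            return self.n_features
        return feature_dimension(self.feature_config.pattern)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Ensemble score ``sum_t alpha_t h_t(x)`` for each row of X."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dimension {X.shape} incompatible with model "
                f"(expects {self.feature_dim})"
            )
        score = np.zeros(X.shape[0])
        for s in self.stumps:
            score += s.alpha * s.predict(X)
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 where the score strictly exceeds the threshold, else -1."""
        return np.where(self.decision_function(X) > self.score_threshold, 1, -1)


def sample_training_pixels(
    images: Sequence[RasterImage],
    masks: Sequence[BinaryMask],
    feature_config: FeatureConfig,
    neg_pos_ratio: float = 3.0,
    max_pos_per_image: int = 2000,
    seed: int = 0,
    exclusion_margin_px: float = 5.0,
) -> list[PixelSample]:
    """Draw labeled pixels from image/mask pairs, features included.

    Positives are drawn uniformly without replacement from mask-true pixels
    (capped per image); negatives, ``neg_pos_ratio`` times as many, from
    pixels farther than ``exclusion_margin_px`` from any mask-true pixel,
    which keeps blurred cell borders out of the negative class.  Images are
    illumination-corrected before feature extraction, matching prediction.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired")
    samples: list[PixelSample] = []
    root = np.random.SeedSequence(seed)
    for i, (image, mask) in enumerate(zip(images, masks)):
        if mask.pixels.shape != (image.height, image.width):
            raise ValueError(
                f"mask {mask.id!r} shape {mask.pixels.shape} does not match "
                f"image {image.id!r} ({image.height}, {image.width})"
            )
        if not mask.pixels.any():
            logger.warning("mask of image %r has no positive pixels; skipped", image.id)
            continue
        rng = np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,)))
        pos_coords = np.argwhere(mask.pixels)
        n_pos = min(len(pos_coords), max_pos_per_image)
        pos_coords = pos_coords[
            rng.choice(len(pos_coords), size=n_pos, replace=False)
        ]
        dist = distance_transform_edt(~mask.pixels)
        neg_pool = np.argwhere(dist > exclusion_margin_px)
        n_neg = min(len(neg_pool), int(round(neg_pos_ratio * n_pos)))
        neg_coords = neg_pool[rng.choice(len(neg_pool), size=n_neg, replace=False)]

        corrected = correct_illumination(image, feature_config.illumination)
        stack = compute_channel_stack(corrected)
        anchors = np.vstack([pos_coords, neg_coords])
        X = extract_feature_matrix(stack, anchors, feature_config.pattern)
        labels = np.r_[np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)]
        for (r, c), x, y in zip(anchors, X, labels):
            samples.append(PixelSample(features=x, label=int(y), source=(image.id, int(r), int(c))))
    if not any(s.label == 1 for s in samples):
        raise ValueError("no positive training pixels found in any image")
    return samples


def _best_stump(
    Xs: np.ndarray, sort_idx: np.ndarray, w: np.ndarray, y: np.ndarray
) -> tuple[int, float, int, float]:
    """Exact minimum-weighted-error stump over all features and midpoints.

    ``Xs`` holds each feature's values already sorted (F, N); ``sort_idx`` the
    corresponding argsort.  For a cut after sorted position i, the classifier
    "+1 iff x > t" errs with weight ``W_neg + cumsum(w*y)[i]``; the opposite
    polarity errs with one minus that.  Ties break toward the smaller feature
    index, then the smaller threshold, then polarity +1.
    """
    wy = (w * y)[sort_idx]  # (F, N)
    cum = np.cumsum(wy, axis=1)[:, :-1]
    w_neg = float(w[y == -1].sum())
    valid = np.diff(Xs, axis=1) > 0
    err_pos = np.where(valid, w_neg + cum, np.inf)
    err_neg = np.where(valid, 1.0 - (w_neg + cum), np.inf)

    flat_pos = int(np.argmin(err_pos))
    flat_neg = int(np.argmin(err_neg))
    best_pos = err_pos.ravel()[flat_pos]
    best_neg = err_neg.ravel()[flat_neg]
    if best_pos <= best_neg:
        flat, polarity, eps = flat_pos, 1, best_pos
    else:
        flat, polarity, eps = flat_neg, -1, best_neg
    if not np.isfinite(eps):
        raise ValueError("no valid stump threshold (all features constant)")
    f, i = divmod(flat, err_pos.shape[1])
    threshold = float((Xs[f, i] + Xs[f, i + 1]) / 2.0)
    return int(f), threshold, polarity, float(eps)


def train_adaboost(
    samples: Sequence[PixelSample] | tuple[np.ndarray, np.ndarray],
    n_rounds: int = 200,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    score_threshold: float = 0.0,
) -> BoostModel:
    """Fit a discrete-AdaBoost stump ensemble on labeled pixel samples.

    ``samples`` may be a list of :class:`PixelSample` or a pre-stacked
    ``(X, y)`` pair.  Training is fully deterministic given the sample order
    (the stump search is exhaustive; ``seed`` is recorded for provenance of
    the sampling stage).
    """
    if isinstance(samples, tuple):
        X, y = samples
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
    else:
        X = np.asarray([s.features for s in samples], dtype=np.float64)
        y = np.asarray([s.label for s in samples], dtype=np.int64)
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (N, F) with one label per row")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("training data must contain both classes")

    sort_idx = np.argsort(X, axis=0, kind="stable").T  # (F, N)
    Xs = np.take_along_axis(X.T, sort_idx, axis=1)

    n = len(y)
    w = np.full(n, 1.0 / n)
    stumps: list[DecisionStump] = []
    train_errors: list[float] = []
    agg = np.zeros(n)
    for _ in range(n_rounds):
        f, thr, pol, eps = _best_stump(Xs, sort_idx, w, y)
        if eps >= 0.5:
            logger.info("stopping early: best stump error %.4f >= 0.5", eps)
            break
        eps_c = min(max(eps, EPS_CLAMP), 1.0 - EPS_CLAMP)
        alpha = 0.5 * math.log((1.0 - eps_c) / eps_c)
        stump = DecisionStump(feature_index=f, threshold=thr, polarity=pol, alpha=alpha)
        stumps.append(stump)
        h = stump.predict(X)
        w = w * np.exp(-alpha * y * h)
        w /= w.sum()
        agg += alpha * h
        train_errors.append(float(np.mean(np.where(agg > 0, 1, -1) != y)))
        if eps <= 0.0:  # perfect stump: the ensemble cannot improve
            break

    if feature_config is None:
        feature_config = FeatureConfig(
            pattern=NeighborhoodPattern(offsets=()), illumination=IlluminationConfig()
        )
    return BoostModel(
        stumps=stumps,
        feature_config=feature_config,
        n_rounds=n_rounds,
        seed=seed,
        score_threshold=score_threshold,
        n_features=X.shape[1],
        train_errors=train_errors,
    )


def predict_scores(
    image: RasterImage,
    model: BoostModel,
    illum: IlluminationConfig | None = None,
) -> np.ndarray:
    """Ensemble score of every pixel of a frame (H x W float grid).

    Runs the full pipeline — illumination correction, channel stack, per-pixel
    features — but evaluates stump by stump on shifted channel grids instead
    of materializing the dense feature matrix, which keeps memory flat.
    """
    illum = illum or model.feature_config.illumination
    corrected = correct_illumination(image, illum)
    stack = compute_channel_stack(corrected)
    return score_grid_from_stack(stack, model)


def score_grid_from_stack(stack: ChannelStack, model: BoostModel) -> np.ndarray:
    H, W = stack.full_shape
    pattern = model.feature_config.pattern
    n_s = pattern.n_samples
    sample_offsets = [(0, 0), *pattern.offsets]
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    score = np.zeros((H, W))
    index_cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}
    for s in model.stumps:
        if not 0 <= s.feature_index < model.feature_dim:
            raise ValueError(f"stump feature index {s.feature_index} out of range")
        level, rem = divmod(s.feature_index, CHANNELS_PER_LEVEL * n_s)
        channel, sample = divmod(rem, n_s)
        dr, dc = sample_offsets[sample]
        key = (level, dr, dc)
        if key not in index_cache:
            scale = LEVEL_SCALES[level]
            h, w = stack.levels[level][0].shape
            rr = np.clip((rows + dr) // scale, 0, h - 1)
            cc = np.clip((cols + dc) // scale, 0, w - 1)
            index_cache[key] = (rr, cc)
        rr, cc = index_cache[key]
        vals = stack.levels[level][channel][rr, cc]
        score += np.where(s.polarity * (vals - s.threshold) > 0, s.alpha, -s.alpha)
    return score


def threshold_scores(scores: np.ndarray, score_threshold: float = 0.0) -> BinaryMask:
    """Binarize a score grid; ties at the threshold go to non-CTC."""
    return BinaryMask(pixels=np.asarray(scores) > score_threshold)


def save_model(model: BoostModel, path: str | Path) -> None:
    payload = {
        "version": MODEL_FORMAT_VERSION,
        "n_rounds": model.n_rounds,
        "seed": model.seed,
        "score_threshold": model.score_threshold,
        "n_features": model.n_features,
        "feature_config": model.feature_config.to_dict(),
        "stumps": [
            {
                "feature_index": s.feature_index,
                "threshold": s.threshold,
                "polarity": s.polarity,
                "alpha": s.alpha,
            }
            for s in model.stumps
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> BoostModel:
    try:
        payload = json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read model file {path}: {exc}") from exc
    if "version" not in payload:
        raise ValueError(f"model file {path} lacks a version field")
    if payload["version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has version {payload['version']}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    try:
        stumps = [
            DecisionStump(
                feature_index=int(s["feature_index"]),
                threshold=float(s["threshold"]),
                polarity=int(s["polarity"]),
                alpha=float(s["alpha"]),
            )
            for s in payload["stumps"]
        ]
        return BoostModel(
            stumps=stumps,
            feature_config=FeatureConfig.from_dict(payload["feature_config"]),
            n_rounds=int(payload["n_rounds"]),
            seed=int(payload["seed"]),
            score_threshold=float(payload["score_threshold"]),
            n_features=payload.get("n_features"),
        )
    except KeyError as exc:
        raise ValueError(f"model file {path} is missing field {exc}") from exc
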