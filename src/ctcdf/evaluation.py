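"""Object-level evaluation of CTC detections against fluorescence ground truth.

Detections and ground-truth objects from the same frame are matched greedily
one-to-one in decreasing overlap order; a pair is matchable when the overlap
covers at least a quarter of the smaller object.  Matched ground truth counts
as TP, unmatched ground truth as FN, unmatched detections as FP.

Because the non-tumor cells in a frame are not individually enumerated, the
negative class is *estimated*: the total object count is taken as
``n_images x avg_cells_per_image`` (1270 cells per frame on average for this
kind of preparation), and estimated TN = total - ground-truth CTCs - FP.
Sensitivity, FN rate, estimated FP rate, estimated specificity and estimated
accuracy follow from the confusion counts.

Rates are kept at full precision; :meth:`MetricsReport.printed` truncates
toward zero at the customary precision (two decimals for percentages, four
for the estimated FP rate), the convention under which the derived rates are
consistent with their integer counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .postprocess import DetectedObject

logger = logging.getLogger(__name__)

DEFAULT_AVG_CELLS_PER_IMAGE = 1270.0
DEFAULT_OVERLAP_THRESHOLD = 0.25


@dataclass
class ConfusionCounts:
    """Object-level confusion counts, per image or aggregated."""

    TP: int = 0
    FN: int = 0
    FP: int = 0
    n_images: int = 1
    avg_cells_per_image: float = DEFAULT_AVG_CELLS_PER_IMAGE

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_gt(self) -> int:
        return self.TP + self.FN


@dataclass
class MetricsReport:
    """Derived detection rates, on the percentage scale where noted."""

    sensitivity_pct: float
    fn_rate_pct: float
    est_fp_rate: float  # printed x100 scale, like the percentages
    est_specificity_pct: float
    est_accuracy_pct: float
    counts: ConfusionCounts | None = None

    def printed(self) -> dict[str, float]:
        """Rates truncated toward zero at the customary printed precision."""
        return {
            "sensitivity_pct": _truncate(self.sensitivity_pct, 2),
            "fn_rate_pct": _truncate(self.fn_rate_pct, 2),
            "est_fp_rate": _truncate(self.est_fp_rate, 4),
            "est_specificity_pct": _truncate(self.est_specificity_pct, 2),
            "est_accuracy_pct": _truncate(self.est_accuracy_pct, 2),
        }

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "sensitivity_pct",
                "fn_rate_pct",
                "est_fp_rate",
                "est_specificity_pct",
                "est_accuracy_pct",
            )
        }
        if self.counts is not None:
            d["counts"] = asdict(self.counts)
        return d


def _truncate(value: float, decimals: int) -> float:
    scale = 10**decimals
    return math.trunc(value * scale) / scale


def _overlap(a: DetectedObject, b: DetectedObject) -> int:
    if a.pixels is None or b.pixels is None:
        raise ValueError("objects must carry pixel coordinates for matching")
    sa = {tuple(p) for p in a.pixels}
    sb = {tuple(p) for p in b.pixels}
    return len(sa & sb)


def match_objects(
    detections: Sequence[DetectedObject],
    gt_objects: Sequence[DetectedObject],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    avg_cells_per_image: float = DEFAULT_AVG_CELLS_PER_IMAGE,
) -> ConfusionCounts:
    """Greedy one-to-one matching of detections to ground-truth objects.

    Candidate pairs with ``|det ∩ gt| / min(|det|, |gt|) >= overlap_threshold``
    are taken in decreasing overlap-ratio order; each object matches at most
    once.  Ties in ratio break deterministically by (detection, gt) list
    order.
    """
    pairs = []
    for di, det in enumerate(detections):
        for gi, gt in enumerate(gt_objects):
            inter = _overlap(det, gt)
            if inter == 0:
                continue
            ratio = inter / min(det.pixel_count, gt.pixel_count)
            if ratio >= overlap_threshold:
                pairs.append((ratio, di, gi))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    det_used = set()
    gt_used = set()
    tp = 0
    for _, di, gi in pairs:
        if di in det_used or gi in gt_used:
            continue
        det_used.add(di)
        gt_used.add(gi)
        tp += 1
    return ConfusionCounts(
        TP=tp,
        FN=len(gt_objects) - tp,
        FP=len(detections) - tp,
        n_images=1,
        avg_cells_per_image=avg_cells_per_image,
    )


def aggregate(counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Field-wise sum over per-image counts."""
    if not counts:
        return ConfusionCounts(TP=0, FN=0, FP=0, n_images=0)
    avg = counts[0].avg_cells_per_image
    return ConfusionCounts(
        TP=sum(c.TP for c in counts),
        FN=sum(c.FN for c in counts),
        FP=sum(c.FP for c in counts),
        n_images=len(counts),
        avg_cells_per_image=avg,
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, FN rate, and the estimated-negative-class rates.

    ``N_total = n_images * avg_cells_per_image`` estimates the number of cell
    objects across the evaluated frames; estimated TN excludes the true CTCs:
    ``TN_est = N_total - n_gt - FP``.
    """
    if counts.n_gt <= 0:
        raise ValueError("sensitivity is undefined with no ground-truth objects")
    if counts.n_images <= 0:
        raise ValueError("n_images must be positive")
    n_total = counts.n_images * counts.avg_cells_per_image
    tn_est = n_total - counts.n_gt - counts.FP
    return MetricsReport(
        sensitivity_pct=100.0 * counts.TP / counts.n_gt,
        fn_rate_pct=100.0 * counts.FN / counts.n_gt,
        est_fp_rate=100.0 * counts.FP / n_total,
        est_specificity_pct=100.0 * tn_est / (tn_est + counts.FP),
        est_accuracy_pct=100.0 * (counts.TP + tn_est) / n_total,
        counts=counts,
    )


def evaluate_detections(
    per_image: dict[str, tuple[Sequence[DetectedObject], Sequence[DetectedObject]]],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    avg_cells_per_image: float = DEFAULT_AVG_CELLS_PER_IMAGE,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Match and score many frames at once.

    ``per_image`` maps an image id to its (detections, ground-truth objects).
    Returns the aggregate report plus a per-image counts table with columns
    ``image, TP, FN, FP, n_gt`` (sorted by image id, so the result does not
    depend on input ordering).
    """
    rows = []
    counts = []
    for image_id in sorted(per_image):
        dets, gts = per_image[image_id]
        c = match_objects(
            dets,
            gts,
            overlap_threshold=overlap_threshold,
            avg_cells_per_image=avg_cells_per_image,
        )
        counts.append(c)
        rows.append(
            {"image": image_id, "TP": c.TP, "FN": c.FN, "FP": c.FP, "n_gt": c.n_gt}
        )
    report = compute_metrics(aggregate(counts))
    return report, pd.DataFrame(rows, columns=["image", "TP", "FN", "FP", "n_gt"])


def write_metrics(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
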