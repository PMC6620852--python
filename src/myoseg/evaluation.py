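"""Per-fiber precision/recall/F1 with fixed- and dynamic-threshold modes.

A probability map is binarized at a threshold and its 8-connected
components (above a minimum area) become predicted fibers S.  Every
ground-truth fiber G is matched to the prediction with the largest
overlap; per fiber, precision = |S n G| / |S| and recall = |S n G| / |G|
(both 0 if nothing overlaps).  Image-level precision and recall are the
means over that image's fibers, and F1 = 2PR / (P + R) is computed from
those image means.

Two summaries over a test set:

* FT (fixed threshold): the single threshold from a grid that maximizes
  the mean F1 across images; metrics reported at that threshold.
* DT (dynamic threshold): each image uses its own best-F1 threshold.

By construction the DT mean F1 is always >= the FT mean F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FiberMetrics",
    "TestSummary",
    "DEFAULT_MIN_AREA",
    "default_threshold_grid",
    "binarize_and_label",
    "image_metrics",
    "ft_dt_summary",
]

DEFAULT_MIN_AREA = 30
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class FiberMetrics:
    """Fiber-averaged metrics of one image at one threshold."""

    threshold: float
    precision: float
    recall: float
    f1: float
    n_fibers: int


@dataclass
class TestSummary:
    """Mean +- sigma of P/R/F1 over test images, FT and DT modes."""

    ft_threshold: float
    ft: dict  # metric -> (mean, std)
    dt: dict
    per_image_ft: list = field(default_factory=list)  # FiberMetrics per image
    per_image_dt: list = field(default_factory=list)


def _f1(p: float, r: float) -> float:
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def binarize_and_label(prob: np.ndarray, threshold: float, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Threshold at ``prob >= t`` and label 8-connected components.

    Components smaller than ``min_area`` pixels are discarded; surviving
    components are relabeled 1..K in scan order.
    """
    if not (0.0 <= threshold <= 1.0 + 1e-9):
        raise ValueError("threshold must lie in [0, 1]")
    fg = np.asarray(prob) >= threshold
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = areas >= min_area
    keep[0] = False
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels]


def image_metrics(pred_labels: np.ndarray, gt_labels: np.ndarray, threshold: float = float("nan")) -> Optional[FiberMetrics]:
    """Fiber-averaged precision/recall/F1 of one labeled prediction.

    Each ground-truth fiber is matched to the predicted region with the
    largest pixel overlap (ties go to the lower predicted label id); a
    fiber with no overlapping prediction scores 0/0.  Returns ``None``
    for an image without ground-truth fibers (excluded upstream with a
    warning).
    """
    pred = np.asarray(pred_labels)
    gt = np.asarray(gt_labels)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    n_gt = int(gt.max())
    if n_gt == 0:
        return None
    n_pred = int(pred.max())
    gt_areas = np.bincount(gt.ravel(), minlength=n_gt + 1)
    precisions = np.zeros(n_gt)
    recalls = np.zeros(n_gt)
    if n_pred > 0:
        pred_areas = np.bincount(pred.ravel(), minlength=n_pred + 1)
        # joint histogram of (gt id, pred id) pixel pairs
        joint = gt.astype(np.int64).ravel() * (n_pred + 1) + pred.astype(np.int64).ravel()
        counts = np.bincount(joint, minlength=(n_gt + 1) * (n_pred + 1)).reshape(n_gt + 1, n_pred + 1)
        overlap = counts[1:, 1:]  # gt fibers x predicted regions
        for g in range(n_gt):
            row = overlap[g]
            best = int(row.argmax())  # first maximum -> lowest pred id on ties
            inter = row[best]
            if inter > 0:
                precisions[g] = inter / pred_areas[best + 1]
                recalls[g] = inter / gt_areas[g + 1]
    p = float(precisions.mean())
    r = float(recalls.mean())
    return FiberMetrics(threshold=threshold, precision=p, recall=r, f1=_f1(p, r), n_fibers=n_gt)


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def ft_dt_summary(
    prob_maps: Sequence[np.ndarray],
    gt_labels: Sequence[np.ndarray],
    threshold_grid: Optional[Sequence[float]] = None,
    min_area: int = DEFAULT_MIN_AREA,
) -> TestSummary:
    """Fixed- and dynamic-threshold summaries over a test set.

    Evaluates every image at every grid threshold once; FT picks the
    grid point maximizing the mean F1, DT picks each image's best-F1
    threshold (ties at a given F1 go to the lower threshold).
    """
    grid = np.asarray(threshold_grid if threshold_grid is not None else default_threshold_grid(), dtype=float)
    if len(prob_maps) == 0:
        raise ValueError("empty test set")
    if len(prob_maps) != len(gt_labels):
        raise ValueError("prob_maps and gt_labels must have the same length")
    table: list[list[FiberMetrics]] = []  # [image][threshold]
    for prob, gt in zip(prob_maps, gt_labels):
        row = []
        for t in grid:
            m = image_metrics(binarize_and_label(prob, float(t), min_area), gt, threshold=float(t))
            if m is None:
                warnings.warn("image without ground-truth fibers excluded from the summary")
                row = None
                break
            row.append(m)
        if row is not None:
            table.append(row)
    if not table:
        raise ValueError("no image with ground-truth fibers in the test set")
    f1 = np.array([[m.f1 for m in row] for row in table])  # images x thresholds
    ft_idx = int(f1.mean(axis=0).argmax())
    per_image_ft = [row[ft_idx] for row in table]
    per_image_dt = [row[int(np.argmax([m.f1 for m in row]))] for row in table]

    def stats(ms: list[FiberMetrics]) -> dict:
        return {
            name: (float(np.mean(vals)), float(np.std(vals)))
            for name, vals in (
                ("precision", [m.precision for m in ms]),
                ("recall", [m.recall for m in ms]),
                ("f1", [m.f1 for m in ms]),
            )
        }

    return TestSummary(
        ft_threshold=float(grid[ft_idx]),
        ft=stats(per_image_ft),
        dt=stats(per_image_dt),
        per_image_ft=per_image_ft,
        per_image_dt=per_image_dt,
    )
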