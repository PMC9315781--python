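"""Fish detection: boxes, size extraction, losses, and AP evaluation.

The detector seat is a small protocol — anything with
``detect(scene) -> list[Detection]`` — with two shipped backends:

* :class:`OracleDetector` reads a rendered scene's ground-truth
  annotations and applies configurable box jitter and a score model; it is
  the reference backend for exercising the downstream pipeline.
* :class:`ThresholdDetector` is a pixel backend: background subtraction,
  Otsu binarisation, connected components, and solidity-scored boxes.

Alongside sit the evaluation pieces used to characterise any backend:
intersection-over-union, COCO-style average precision (101-point
interpolated, averaged over IoU thresholds 0.50:0.05:0.95), and the
multi-task detector training losses (classification negative
log-likelihood, smooth-L1 box loss, per-pixel binary cross-entropy mask
loss) as pure evaluable formulas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Protocol, runtime_checkable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BBox",
    "Detection",
    "EvalConfig",
    "SizePx",
    "bbox_to_size",
    "filter_by_score",
    "iou",
    "average_precision",
    "ap_summary",
    "class_loss",
    "smooth_l1",
    "bbox_loss",
    "mask_loss",
    "total_loss",
    "DetectorProtocol",
    "OracleDetector",
    "ThresholdDetector",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel intervals."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate bbox {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Detection:
    """A scored box, optionally with an m x m instance mask."""

    bbox: BBox
    score: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("mask must be a square matrix")


@dataclass(frozen=True)
class EvalConfig:
    iou_thresholds: tuple = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
    score_threshold: float = 0.8

    def __post_init__(self):
        t = self.iou_thresholds
        if not all(0 < x <= 1 for x in t) or list(t) != sorted(t):
            raise ValueError("iou_thresholds must be sorted values in (0, 1]")


class SizePx(NamedTuple):
    length_px: float
    width_px: float
    swapped: bool = False


def bbox_to_size(bbox: BBox) -> SizePx:
    """Fish length/width in pixels from a box.

    Length is the horizontal extent and width the vertical one (fish are
    assumed to swim horizontally); a taller-than-wide box is treated as a
    vertically aligned fish — the two extents are swapped and the
    ``swapped`` flag set (and logged) rather than failing.
    """
    length, width = bbox.width, bbox.height
    if width > length:
        logger.warning("vertical fish: swapping box extents %.1f x %.1f", length, width)
        return SizePx(width, length, True)
    return SizePx(length, width, False)


def filter_by_score(detections, threshold: float = 0.8) -> list[Detection]:
    """Keep detections with score >= threshold (order preserved)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [d for d in detections if d.score >= threshold]


def iou(b1: BBox, b2: BBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = min(b1.x_max, b2.x_max) - max(b1.x_min, b2.x_min)
    iy = min(b1.y_max, b2.y_max) - max(b1.y_min, b2.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (b1.area + b2.area - inter)


def _match(detections, ground_truths, iou_threshold: float):
    """Greedy score-descending matching; each ground truth used at most once.

    Returns boolean true-positive flags in score order.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].score)  # stable: ties keep input order
    taken = [False] * len(ground_truths)
    tp = np.zeros(len(detections), dtype=bool)
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truths):
            if taken[j]:
                continue
            v = iou(detections[i].bbox, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            tp[rank] = True
    return tp


def average_precision(detections, ground_truths, iou_threshold: float) -> float:
    """Average precision at one IoU threshold, 101-point interpolated.

    Conventions for empty inputs: no ground truths and no detections is a
    vacuous perfect result (1.0, logged); detections without any ground
    truth score 0.0, as do ground truths without detections.
    """
    if not ground_truths:
        if not detections:
            logger.info("AP on empty scene with no detections: 1.0 by convention")
            return 1.0
        return 0.0
    if not detections:
        return 0.0
    tp = _match(detections, ground_truths, iou_threshold)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    recall = tp_cum / len(ground_truths)
    precision = tp_cum / (tp_cum + fp_cum)
    points = np.linspace(0.0, 1.0, 101)
    interp = np.zeros_like(points)
    for k, r in enumerate(points):
        mask = recall >= r - 1e-12
        if mask.any():
            interp[k] = precision[mask].max()
    return float(interp.mean())


def ap_summary(detections, ground_truths,
               config: EvalConfig | None = None) -> tuple[float, float, float]:
    """(AP averaged over the threshold sweep, AP at 0.50, AP at 0.75)."""
    config = config or EvalConfig()
    aps = [average_precision(detections, ground_truths, t)
           for t in config.iou_thresholds]
    ap50 = average_precision(detections, ground_truths, 0.50)
    ap75 = average_precision(detections, ground_truths, 0.75)
    return float(np.mean(aps)), ap50, ap75


# --- multi-task training losses (pure formulas) -------------------------

def class_loss(p_u: float) -> float:
    """Classification loss -ln(p_u) for the true-class probability."""
    if not 0.0 < p_u <= 1.0:
        raise ValueError("p_u must lie in (0, 1]")
    return -math.log(p_u)


def smooth_l1(x: float) -> float:
    """0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    x = float(x)
    return 0.5 * x * x if abs(x) < 1.0 else abs(x) - 0.5


def bbox_loss(t_u, v) -> float:
    """Smooth-L1 box regression loss summed over (x, y, w, h)."""
    t_u = np.asarray(t_u, dtype=float)
    v = np.asarray(v, dtype=float)
    if t_u.shape != (4,) or v.shape != (4,):
        raise ValueError("bbox_loss expects two 4-vectors (x, y, w, h)")
    return float(sum(smooth_l1(d) for d in t_u - v))


def mask_loss(pred_mask, true_mask) -> float:
    """Average per-pixel binary cross-entropy between mask probabilities and truth."""
    p = np.asarray(pred_mask, dtype=float)
    y = np.asarray(true_mask, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {y.shape}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predicted mask probabilities must lie in (0, 1)")
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(bce.mean())


def total_loss(l_class: float, l_bb: float, l_mask: float,
               weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Weighted total of the three task losses (unit weights by default)."""
    parts = (l_class, l_bb, l_mask)
    if any(x < 0 for x in parts):
        raise ValueError("loss components must be non-negative")
    return float(sum(w * x for w, x in zip(weights, parts)))


# --- detector backends --------------------------------------------------

@runtime_checkable
class DetectorProtocol(Protocol):
    def detect(self, scene) -> list[Detection]:  # pragma: no cover - protocol
        ...


class OracleDetector:
    """Reads a rendered scene's ground truth, with optional jitter and score noise.

    With ``jitter_px = 0`` and a deterministic score the detections equal
    the annotations exactly, giving AP 1.0 on every scene — the reference
    upper bound for pipeline tests.
    """

    def __init__(self, jitter_px: float = 0.0, score_mean: float = 0.99,
                 score_sd: float = 0.0, seed: int = 0):
        self.jitter_px = jitter_px
        self.score_mean = score_mean
        self.score_sd = score_sd
        self._rng = np.random.default_rng(seed)

    def detect(self, scene) -> list[Detection]:
        h, w = scene.image.shape[:2]
        out = []
        for ann in scene.annotations:
            x0, y0, x1, y1 = ann.bbox
            if self.jitter_px > 0:
                dx0, dy0, dx1, dy1 = self._rng.uniform(
                    -self.jitter_px, self.jitter_px, 4)
                x0 = min(max(x0 + dx0, 0), w - 1)
                y0 = min(max(y0 + dy0, 0), h - 1)
                x1 = min(max(x1 + dx1, x0 + 1), w)
                y1 = min(max(y1 + dy1, y0 + 1), h)
            score = self.score_mean
            if self.score_sd > 0:
                score = float(np.clip(
                    self._rng.normal(self.score_mean, self.score_sd), 0.0, 1.0))
            out.append(Detection(bbox=BBox(x0, y0, x1, y1), score=score))
        return out


class ThresholdDetector:
    """Classical pixel backend: binarise against the background, label components.

    Grayscale conversion, Otsu threshold (foreground assumed brighter than
    the water background), connected-component labelling, and one box per
    component of sufficient area.  The detection score is the component's
    solidity (area / convex area), a cheap shape-quality proxy in [0, 1].
    """

    def __init__(self, min_area_px: float = 400.0, threshold: float | None = None):
        self.min_area_px = min_area_px
        self.threshold = threshold

    def detect(self, scene) -> list[Detection]:
        from skimage.filters import threshold_otsu
        from skimage.measure import label, regionprops

        image = getattr(scene, "image", scene)
        gray = np.asarray(image, dtype=float).mean(axis=2)
        thr = self.threshold
        if thr is None:
            if np.ptp(gray) == 0:  # blank scene: nothing to separate
                return []
            thr = threshold_otsu(gray)
        foreground = gray > thr
        out = []
        for region in regionprops(label(foreground)):
            if region.area < self.min_area_px:
                continue
            r0, c0, r1, c1 = region.bbox
            score = float(min(region.solidity, 1.0))
            out.append(Detection(bbox=BBox(c0, r0, c1, r1), score=score))
        return out
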