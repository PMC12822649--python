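"""Fovea localization within a B-scan.

Two backends share one contract (return a :class:`Detection` or
``None``):

* ``baseline_detect`` — a deterministic pit finder: extract the inner
  retinal surface as the first supra-threshold row per column, median
  smooth, fit a low-order polynomial baseline, and report the deepest
  depression.  It needs no training data, so the whole pipeline is
  testable offline, and it doubles as the reference oracle for the
  learned backend.
* a learned single-stage object detector trained on annotated foveal
  B-scans (recipe: 292 training / 39 validation images, 30 epochs).
  The recipe is recorded verbatim in :class:`DetectorRecipe`; the
  backend is optional and requires the ``ultralytics`` package and the
  external annotation set, neither of which this package ships.

Evaluation uses greedy confidence-descending IoU matching, the standard
protocol behind detection precision/recall figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import medfilt

from .errors import ParameterError


@dataclass(frozen=True)
class Detection:
    """Axis-aligned box (0-based, half-open) with a confidence score."""

    box: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max
    confidence: float
    class_label: str = "fovea"

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise ParameterError("box: must have positive extent")
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError("confidence: must be in [0, 1]")


@dataclass(frozen=True)
class DetectorRecipe:
    """Training recipe of the learned detector, logged verbatim."""

    epochs: int = 30
    train_set_size: int = 292
    val_set_size: int = 39
    backend: str = "baseline"  # "baseline" | "learned"


def _surface_profile(image: np.ndarray, threshold: float) -> np.ndarray | None:
    """First supra-threshold row per column (float NaN where none)."""
    above = image > threshold
    any_above = above.any(axis=0)
    if not any_above.any():
        return None
    first = np.argmax(above, axis=0).astype(float)
    first[~any_above] = np.nan
    return first


def baseline_detect(bscan: np.ndarray, min_pit_depth_px: float = 6.0,
                    smooth: int = 7, baseline_degree: int = 2,
                    ) -> Detection | None:
    """Detect the foveal pit in a grayscale B-scan, if present.

    The inner surface is taken as the first row per column brighter than
    the midpoint of the image intensity range, median-smoothed over
    ``smooth`` columns, and compared against a degree-
    ``baseline_degree`` polynomial baseline (fitted twice, the second
    time excluding the candidate pit so a deep pit does not drag the
    baseline down).  The deepest depression, if at least
    ``min_pit_depth_px`` rows, is returned as a box spanning the
    half-depth column support; confidence is the depth as a fraction of
    the image height.  Equal-depth pits resolve to the earliest column.
    """
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise ParameterError("bscan: expected a 2-D grayscale image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-6:
        return None  # blank image

    surface = _surface_profile(img, lo + 0.5 * (hi - lo))
    if surface is None:
        return None
    # fill missing columns by nearest valid neighbour
    if np.isnan(surface).any():
        idx = np.arange(surface.size)
        valid = ~np.isnan(surface)
        surface = np.interp(idx, idx[valid], surface[valid])
    if smooth > 1:
        surface = medfilt(surface, kernel_size=smooth | 1)

    cols = np.arange(surface.size, dtype=float)

    # the pit is a localized *downward* bump (larger rows) on a slowly
    # varying surface, so the baseline is fitted by asymmetric least
    # squares: residuals above the running fit are heavily downweighted,
    # which drives the polynomial onto the un-dipped lower envelope
    coeffs = np.polyfit(cols, surface, baseline_degree)
    for _ in range(20):
        above = surface > np.polyval(coeffs, cols) + 0.5
        weights = np.where(above, 0.03, 1.0)
        new_coeffs = np.polyfit(cols, surface, baseline_degree, w=weights)
        if np.allclose(new_coeffs, coeffs):
            break
        coeffs = new_coeffs
    dep = surface - np.polyval(coeffs, cols)
    depth = dep.max()
    if depth < min_pit_depth_px:
        return None

    # locate the deepest depression; among equal-depth pits (within half
    # a pixel) the earliest contiguous group wins.  The plateau itself is
    # expanded on the raw surface profile, which is immune to any
    # residual tilt of the fitted baseline.
    near_max = np.flatnonzero(dep >= depth - 0.5)
    splits = np.flatnonzero(np.diff(near_max) > 1)
    group = near_max[:splits[0] + 1] if splits.size else near_max
    peak = int(group[np.argmax(surface[group])])
    level = surface[peak]
    left_p = right_p = peak
    while left_p - 1 >= 0 and surface[left_p - 1] >= level - 0.5:
        left_p -= 1
    while right_p + 1 < surface.size and surface[right_p + 1] >= level - 0.5:
        right_p += 1
    center = int(np.floor((left_p + right_p) / 2 + 0.5))

    # box columns: width of the contiguous half-depth interval through
    # the centre, laid out symmetrically about the (unbiased) plateau
    # centre so residual baseline tilt cannot skew the box midpoint
    support = set(np.flatnonzero(dep >= depth / 2).tolist())
    left = right = center
    while left - 1 in support:
        left -= 1
    while right + 1 in support:
        right += 1
    halfwidth = min((right - left) // 2, center, surface.size - 1 - center)

    row_top = int(np.clip(np.floor(surface[center] - depth), 0, img.shape[0] - 1))
    row_bot = int(np.clip(np.ceil(surface[center]) + 1, row_top + 1, img.shape[0]))
    box = (row_top, center - halfwidth, row_bot, center + halfwidth + 1)
    confidence = float(np.clip(depth / img.shape[0], 0.0, 1.0))
    return Detection(box=box, confidence=confidence)


def fovea_x_from_detection(det: Detection) -> int:
    """Horizontal centre pixel of a detection box.

    For the half-open column interval ``[c0, c1)`` the centre pixel is
    ``(c0 + c1 - 1) / 2`` rounded half-up (the lower middle of an even
    pixel span), e.g. ``[100, 120) -> 110``, ``[0, 1) -> 0``,
    ``[10, 15) -> 12``.
    """
    c0, c1 = det.box[1], det.box[3]
    return int(np.floor((c0 + c1 - 1) / 2 + 0.5))


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ra0, ca0, ra1, ca1 = box_a
    rb0, cb0, rb1, cb1 = box_b
    ih = max(0, min(ra1, rb1) - max(ra0, rb0))
    iw = max(0, min(ca1, cb1) - max(ca0, cb0))
    inter = ih * iw
    union = (ra1 - ra0) * (ca1 - ca0) + (rb1 - rb0) * (cb1 - cb0) - inter
    return inter / union if union > 0 else 0.0


def evaluate_detections(predictions: list[list[Detection]],
                        truths: list[list[tuple[int, int, int, int]]],
                        iou_threshold: float = 0.5) -> tuple[float, float]:
    """Precision and recall under greedy confidence-descending matching.

    Within each image, predictions are visited in decreasing confidence
    (stable for ties); each claims the unmatched ground-truth box of
    highest IoU, and counts as a true positive if that IoU reaches
    ``iou_threshold``.  Precision is TP/(TP+FP) over all predictions,
    recall TP/(TP+FN) over all ground-truth boxes; an empty denominator
    yields 1.0 (vacuous).
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ParameterError("iou_threshold: must be in (0, 1]")
    if len(predictions) != len(truths):
        raise ParameterError("predictions: image count differs from truths")

    tp = fp = n_truth = 0
    for preds, gts in zip(predictions, truths):
        n_truth += len(gts)
        order = sorted(range(len(preds)),
                       key=lambda i: -preds[i].confidence)
        unmatched = list(range(len(gts)))
        for i in order:
            if unmatched:
                ious = np.array([iou(preds[i].box, gts[j]) for j in unmatched])
                best = int(np.argmax(ious))
                if ious[best] >= iou_threshold:
                    del unmatched[best]
                    tp += 1
                    continue
            fp += 1

    n_pred = tp + fp
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return precision, recall


# --------------------------------------------------------------------------
# annotation I/O (normalized "class cx cy w h" text files, one per image)


def write_annotation(path: str | Path, boxes, image_shape,
                     class_id: int = 0) -> None:
    """Write half-open pixel boxes as normalized centre-size lines."""
    h, w = image_shape[:2]
    lines = []
    for r0, c0, r1, c1 in boxes:
        cx, cy = (c0 + c1) / 2 / w, (r0 + r1) / 2 / h
        bw, bh = (c1 - c0) / w, (r1 - r0) / h
        lines.append(f"{class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotation(path: str | Path, image_shape) -> list[tuple[int, int, int, int]]:
    """Read normalized centre-size annotations back to pixel boxes."""
    h, w = image_shape[:2]
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, cx, cy, bw, bh = (float(v) for v in line.split())
        c0 = int(round((cx - bw / 2) * w))
        c1 = int(round((cx + bw / 2) * w))
        r0 = int(round((cy - bh / 2) * h))
        r1 = int(round((cy + bh / 2) * h))
        boxes.append((r0, c0, r1, c1))
    return boxes


def learned_detect(bscan: np.ndarray, model_path: str | Path) -> Detection | None:
    """Run the learned single-stage detector backend, if available.

    Requires the optional ``ultralytics`` dependency and a trained
    weights file; neither ships with this package (the baseline backend
    is the supported offline path).
    """
    try:
        from ultralytics import YOLO  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional backend
        raise ParameterError(
            "learned detector backend requires the optional 'ultralytics' "
            "dependency; use the baseline backend instead") from exc
    model = YOLO(str(model_path))  # pragma: no cover - optional backend
    result = model(np.dstack([bscan] * 3))[0]  # pragma: no cover
    if len(result.boxes) == 0:  # pragma: no cover
        return None
    b = result.boxes[0]  # pragma: no cover
    x0, y0, x1, y1 = (float(v) for v in b.xyxy[0])  # pragma: no cover
    return Detection(box=(int(y0), int(x0), int(np.ceil(y1)), int(np.ceil(x1))),
                     confidence=float(b.conf[0]))  # pragma: no cover
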