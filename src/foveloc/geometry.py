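"""Scan-line geometry: fundus overlay detection and coordinate mapping.

The acquisition software renders a green line on the en-face fundus
image marking where the current B-scan was taken.  Locating that line
gives the fovea's ``y`` coordinate on the fundus; the line's pixels map
1:1 onto the B-scan's columns, so the pit column found in the B-scan
gives the ``x`` coordinate.  Subtracting the previously recorded
reference-marker pixel and scaling by mm/px yields the physical offset
the stage must cancel.

The line detector follows the classic chain: HSV conversion, green-band
masking, edge extraction, and a Hough line transform restricted to
near-horizontal angles; the winning line's row is refined by the
centroid of masked pixels in a narrow band, which makes the result exact
on noiseless renderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.transform import hough_line, hough_line_peaks

from .errors import DetectionError, ParameterError
from .scene import FundusImage


@dataclass(frozen=True)
class ScanLineConfig:
    """Mask and Hough parameters for green scan-line detection.

    Hue bounds are degrees on the 0-360 circle; saturation/value on
    0-1.  ``max_tilt_deg`` bounds the accepted deviation from
    horizontal; ``min_support`` is the minimum number of edge pixels
    voting for the winning line.
    """

    hue_min_deg: float = 90.0
    hue_max_deg: float = 150.0
    sat_min: float = 0.4
    val_min: float = 0.3
    max_tilt_deg: float = 5.0
    min_support: int = 15
    refine_halfwidth: int = 3


@dataclass(frozen=True)
class ScanLineFit:
    """Detected scan-line: row at the image centre column, tilt, votes."""

    row: int
    angle_deg: float
    support: int


@dataclass(frozen=True)
class FoveaLocation:
    """Fovea position on the fundus and relative to the reference marker."""

    fundus_px: tuple[int, int]
    physical_mm: tuple[float, float]  # (x, y)
    source_bscan: int


def green_mask(rgb: np.ndarray, config: ScanLineConfig) -> np.ndarray:
    """Boolean mask of pixels inside the configured green HSV band."""
    hsv = rgb2hsv(np.asarray(rgb, dtype=float))
    hue_deg = hsv[..., 0] * 360.0
    return ((hue_deg >= config.hue_min_deg) & (hue_deg <= config.hue_max_deg)
            & (hsv[..., 1] >= config.sat_min) & (hsv[..., 2] >= config.val_min))


def detect_scan_line(fundus: FundusImage | np.ndarray,
                     config: ScanLineConfig | None = None) -> ScanLineFit:
    """Locate the green scan-line overlay in a fundus image.

    Raises :class:`DetectionError` if no pixel passes the green mask or
    the strongest near-horizontal Hough peak has fewer than
    ``config.min_support`` votes.
    """
    config = config or ScanLineConfig()
    rgb = fundus.pixels if isinstance(fundus, FundusImage) else np.asarray(fundus)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("fundus: expected an RGB image")

    mask = green_mask(rgb, config)
    if not mask.any():
        raise DetectionError("no pixel passes the green scan-line mask")

    edges = canny(mask.astype(float), sigma=1.0)
    if not edges.any():
        edges = mask  # degenerate thin line: vote with the mask itself

    tilt = config.max_tilt_deg
    theta = np.deg2rad(np.linspace(90.0 - tilt, 90.0 + tilt,
                                   max(int(8 * tilt) + 1, 3)))
    accum, thetas, dists = hough_line(edges, theta=theta)
    peaks = hough_line_peaks(accum, thetas, dists, num_peaks=8,
                             threshold=0.5 * accum.max())
    x_c = (rgb.shape[1] - 1) / 2.0
    candidates = []
    for votes, th, rho in zip(*peaks):
        s = np.sin(th)
        if abs(s) < 1e-9:
            continue
        row = (rho - x_c * np.cos(th)) / s
        if 0 <= row < rgb.shape[0]:
            candidates.append((int(votes), float(row), float(np.rad2deg(th) - 90.0)))
    if not candidates:
        raise DetectionError("no near-horizontal line found")
    # strongest peak wins; ties resolve to the smallest row
    candidates.sort(key=lambda c: (-c[0], c[1]))
    votes, row_est, angle = candidates[0]
    if votes < config.min_support:
        raise DetectionError(
            f"scan-line support {votes} below minimum {config.min_support}")

    # refine: centroid of masked rows within a band around the Hough row
    ys = np.nonzero(mask)[0]
    band = ys[np.abs(ys - row_est) <= config.refine_halfwidth]
    row = int(np.rint(band.mean())) if band.size else int(np.rint(row_est))
    return ScanLineFit(row=row, angle_deg=angle, support=votes)


def map_fovea_to_fundus(bscan_col: int, bscan_width: int, line: ScanLineFit,
                        scan_col_start: int, scan_col_end: int,
                        ) -> tuple[int, int]:
    """Map a B-scan column onto the fundus via the 1:1 scan-line match.

    The scan-line pixel span ``[scan_col_start, scan_col_end)``
    corresponds linearly to the B-scan's ``bscan_width`` columns;
    rounding is half-up.  Returns ``(row, col)`` on the fundus.
    """
    if not scan_col_start < scan_col_end:
        raise ParameterError("scan_col_start: must be < scan_col_end")
    if not 0 <= bscan_col < bscan_width:
        raise ParameterError("bscan_col: outside the B-scan width")
    span = scan_col_end - scan_col_start
    col = scan_col_start + int(np.floor(bscan_col * span / bscan_width + 0.5))
    return line.row, col


def fundus_px_to_mm(px: tuple[int, int], reference_px: tuple[int, int],
                    mm_per_px: float) -> tuple[float, float]:
    """Fundus pixel to physical mm relative to the reference marker.

    Axes: ``x`` along columns, ``y`` along rows; returns ``(x_mm, y_mm)``.
    """
    if mm_per_px <= 0:
        raise ParameterError("mm_per_px: must be > 0")
    return ((px[1] - reference_px[1]) * mm_per_px,
            (px[0] - reference_px[0]) * mm_per_px)


def mm_to_fundus_px(mm: tuple[float, float], reference_px: tuple[int, int],
                    mm_per_px: float) -> tuple[int, int]:
    """Inverse of :func:`fundus_px_to_mm` up to pixel quantization."""
    if mm_per_px <= 0:
        raise ParameterError("mm_per_px: must be > 0")
    return (reference_px[0] + int(np.rint(mm[1] / mm_per_px)),
            reference_px[1] + int(np.rint(mm[0] / mm_per_px)))
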