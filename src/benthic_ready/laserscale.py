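"""Red laser-dot detection and pixel-scale estimation.

Three downward-pointing red lasers at a calibrated mutual separation are
photographed in every frame; the ratio of their separation in pixels to
the calibrated separation in centimeters gives the frame's scale in
px/cm.  Detection thresholds the *redness* ``R - max(G, B)`` — plain
red-channel thresholding would also fire on bright white sediment —
keeps 8-connected components within an area band, and returns the
largest blobs' centroids.

Estimation makes no assumption about the laser layout: the scale is the
mean over all point pairs of (pixel distance / calibrated separation),
which is exact for an equilateral layout and a sensible average for any
other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.measure import label, regionprops

from .errors import ScaleUnavailableError
from .images import ImageRecord


@dataclass
class LaserDetection:
    """Detected laser-dot centroids, sorted by blob area (largest first)."""

    points_px: list[tuple[float, float]]  # (row, col)
    blob_areas_px: list[int]

    def __len__(self) -> int:
        return len(self.points_px)


@dataclass
class ScaleEstimate:
    """Pixels-per-centimeter for one frame and how it was obtained."""

    px_per_cm: float
    n_points_used: int
    method: str = "laser"  # "laser" | "metadata"

    @property
    def cm_per_px(self) -> float:
        return 1.0 / self.px_per_cm


def detect_laser_points(
    image: ImageRecord,
    redness_threshold: int = 80,
    min_area: int = 4,
    max_area: int = 500,
    max_points: int = 3,
) -> LaserDetection:
    """Find up to ``max_points`` red laser dots.

    Pixels with ``R - max(G, B) >= redness_threshold`` form the candidate
    mask; 8-connected components with area in ``[min_area, max_area]``
    become blobs.  Blobs are ranked by area descending and truncated to
    the ``max_points`` largest.  An empty detection is a valid result, not
    an error.
    """
    px = image.pixels.astype(np.int16)
    redness = px[:, :, 0] - np.maximum(px[:, :, 1], px[:, :, 2])
    mask = redness >= redness_threshold
    labeled = label(mask, connectivity=2)
    blobs = [
        (float(p.centroid[0]), float(p.centroid[1]), int(p.area))
        for p in regionprops(labeled)
        if min_area <= p.area <= max_area
    ]
    blobs.sort(key=lambda b: -b[2])
    blobs = blobs[:max_points]
    return LaserDetection(
        points_px=[(r, c) for r, c, _ in blobs],
        blob_areas_px=[a for _, _, a in blobs],
    )


def estimate_scale(detection: LaserDetection, calibrated_separation_cm: float) -> ScaleEstimate:
    """Scale from detected dots: mean over point pairs of px distance / calibrated cm.

    Raises
    ------
    ScaleUnavailableError
        Fewer than two points detected; the caller may fall back to the
        metadata's archived cm/pixel value.
    """
    if calibrated_separation_cm <= 0:
        raise ValueError("calibrated_separation_cm must be positive")
    if len(detection) < 2:
        raise ScaleUnavailableError(
            f"need >= 2 laser points to estimate scale, detected {len(detection)}"
        )
    pts = np.asarray(detection.points_px, dtype=float)
    ratios = [
        float(np.hypot(*(pts[i] - pts[j]))) / calibrated_separation_cm
        for i, j in combinations(range(len(pts)), 2)
    ]
    return ScaleEstimate(
        px_per_cm=float(np.mean(ratios)),
        n_points_used=len(detection),
        method="laser",
    )


def scale_from_metadata(original_scale_cm_per_px: float) -> ScaleEstimate:
    """Fallback scale from the archived metadata (cm/pixel -> px/cm)."""
    if original_scale_cm_per_px <= 0:
        raise ValueError("original_scale_cm_per_px must be positive")
    return ScaleEstimate(
        px_per_cm=1.0 / original_scale_cm_per_px, n_points_used=0, method="metadata"
    )
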