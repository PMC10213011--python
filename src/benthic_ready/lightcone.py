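"""Light-cone (illumination falloff) correction by batch z-score normalization.

An artificial light source over the seabed produces a bright central disk
whose intensity drops radially towards the frame edges.  Because the
falloff pattern is a property of the rig, not the scene, it is shared by
neighbouring frames: standardizing every pixel *position* across a batch
of consecutively acquired images (subtract the per-position mean, divide
by the per-position standard deviation) removes the shared pattern while
preserving per-image scene structure.  Batches follow acquisition-time
order; the canonical batch size is 50 frames.

The z-scored rasters are real-valued; :func:`remap_to_display` maps them
back to 8-bit for storage with a symmetric clip at +/- ``clip_sigma``
standard deviations and a linear map onto 0..255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BatchError
from .images import ImageRecord

#: Standard deviations at or below this are treated as zero (static pixel).
EPSILON_STD = 1e-6


@dataclass
class BatchStatistics:
    """Per-pixel-position mean and standard deviation over one batch."""

    mean: np.ndarray  # (H, W, 3) float
    std: np.ndarray  # (H, W, 3) float, population, >= 0
    batch_size: int


def partition_batches(images: list, batch_size: int = 50) -> list[list]:
    """Split a time-sorted image list into consecutive batches.

    Batches are non-overlapping runs of ``batch_size`` images in the given
    order.  A trailing remainder shorter than ``max(2, batch_size // 5)``
    is merged into the previous batch (a tiny batch would make the
    per-position statistics meaningless); a longer remainder stays its own
    batch.

    Raises
    ------
    BatchError
        Fewer than 2 images in total (the z-score is undefined).
    """
    if batch_size < 2:
        raise BatchError(f"batch_size must be >= 2, got {batch_size}")
    n = len(images)
    if n < 2:
        raise BatchError(f"need at least 2 images for z-score normalization, got {n}")
    batches = [list(images[i : i + batch_size]) for i in range(0, n, batch_size)]
    min_tail = max(2, batch_size // 5)
    if len(batches) > 1 and len(batches[-1]) < min_tail:
        tail = batches.pop()
        batches[-1].extend(tail)
    return batches


def zscore_batch(batch: list[ImageRecord]) -> tuple[list[np.ndarray], BatchStatistics]:
    """Standardize every pixel position and channel across the batch.

    For each (row, col, channel), the values across the batch are shifted
    to mean 0 and scaled to unit population variance.  Positions whose
    standard deviation is <= ``EPSILON_STD`` (static pixels) are set to 0.

    Returns the standardized float rasters (same order as the input) and
    the :class:`BatchStatistics` used.

    Raises
    ------
    BatchError
        Fewer than 2 images, or an image whose shape differs from the
        first one's (named in the message).
    """
    if len(batch) < 2:
        raise BatchError(f"z-score needs >= 2 images per batch, got {len(batch)}")
    shape = batch[0].pixels.shape
    for rec in batch[1:]:
        if rec.pixels.shape != shape:
            raise BatchError(
                f"shape mismatch within batch: {rec.filename or '<unnamed>'} has "
                f"{rec.pixels.shape}, expected {shape}"
            )
    stack = np.stack([rec.pixels.astype(np.float64) for rec in batch], axis=0)
    n = len(batch)
    # Intensities are 8-bit integers, so these float64 sums are exact and the
    # statistics are bit-identical under any permutation of the batch.
    total = stack.sum(axis=0)
    total_sq = (stack * stack).sum(axis=0)
    mean = total / n
    var = np.maximum(total_sq / n - mean * mean, 0.0)
    std = np.sqrt(var)  # population std: batch is the whole population
    safe = std > EPSILON_STD
    out = np.zeros_like(stack)
    np.divide(stack - mean, std, out=out, where=safe)
    stats = BatchStatistics(mean=mean, std=std, batch_size=len(batch))
    return [out[i] for i in range(len(batch))], stats


def remap_to_display(standardized: np.ndarray, clip_sigma: float = 3.0) -> np.ndarray:
    """Map a z-scored raster to 8-bit: clip to [-k, +k], then linear to 0..255.

    The map is monotone; 0 (the batch mean) lands on 128 with the
    round-half-up rule used here.  ``clip_sigma`` defaults to 3 — for
    Gaussian-like values the clip discards ~0.3% of the range.
    """
    if clip_sigma <= 0:
        raise ValueError("clip_sigma must be positive")
    clipped = np.clip(standardized, -clip_sigma, clip_sigma)
    scaled = (clipped + clip_sigma) * (255.0 / (2.0 * clip_sigma))
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half up


def correct_batch(
    batch: list[ImageRecord], clip_sigma: float = 3.0
) -> tuple[list[ImageRecord], BatchStatistics]:
    """z-score a batch and remap to displayable 8-bit records (convenience)."""
    rasters, stats = zscore_batch(batch)
    out = [
        rec.with_pixels(remap_to_display(z, clip_sigma=clip_sigma))
        for rec, z in zip(batch, rasters)
    ]
    return out, stats
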