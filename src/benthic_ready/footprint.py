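"""Footprint standardization: rescale to a common px/cm, center-crop to common size.

Frames shot at different altitudes cover different seabed areas, so they
are not comparable sampling units.  The fix has two steps: (1) resample
every frame from its own scale to the dataset's *median* scale, so one
pixel means the same number of centimeters everywhere; (2) center-crop
all rescaled frames to the elementwise minimum height and width over the
set, so every frame covers exactly the same physical footprint.  The crop
target is the per-axis minimum (a minimum *area* alone would not
determine a rectangle) which guarantees the crop fits every frame.

After the stage, all outputs share identical pixel dimensions and scale;
the across-image variance of footprint area is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import BenthicReadyError, GeometryError
from .images import ImageRecord


@dataclass
class FootprintSpec:
    """Dataset-level target geometry.

    ``footprint_m2`` is derived:
    ``(height/scale) * (width/scale) / 10^4`` with the scale in px/cm.
    """

    target_scale_px_per_cm: float
    target_height_px: int
    target_width_px: int

    @property
    def footprint_m2(self) -> float:
        s = self.target_scale_px_per_cm
        return (self.target_height_px / s) * (self.target_width_px / s) / 1e4


def compute_target_scale(scales_px_per_cm: list[float]) -> float:
    """Median scale over the dataset (even count: mean of the central pair).

    The median is robust to the odd frame shot unusually close or far,
    and minimizes the total resampling the set needs.
    """
    if len(scales_px_per_cm) == 0:
        raise BenthicReadyError("cannot compute a target scale from an empty list")
    return float(np.median(np.asarray(scales_px_per_cm, dtype=float)))


def rescale_to_scale(
    image: ImageRecord, from_scale_px_per_cm: float, to_scale_px_per_cm: float
) -> ImageRecord:
    """Resample a frame from its own scale to the target scale.

    Output dimensions are ``round(dim * to_scale / from_scale)`` per axis;
    resampling is bilinear, with Gaussian anti-aliasing when downscaling.
    The frame's physical extent in cm is preserved to within one output
    pixel per axis.

    Raises
    ------
    GeometryError
        If a resulting dimension would drop below 8 px.
    """
    if from_scale_px_per_cm <= 0 or to_scale_px_per_cm <= 0:
        raise ValueError("scales must be positive")
    ratio = to_scale_px_per_cm / from_scale_px_per_cm
    new_h = int(round(image.height_px * ratio))
    new_w = int(round(image.width_px * ratio))
    if new_h < 8 or new_w < 8:
        raise GeometryError(
            f"rescaling {image.height_px}x{image.width_px} by {ratio:.4f} yields "
            f"{new_h}x{new_w} px (< 8 px); target scale too small for this frame"
        )
    if (new_h, new_w) == (image.height_px, image.width_px):
        return image.with_pixels(image.pixels.copy())
    out = resize(
        image.pixels,
        (new_h, new_w, 3),
        order=1,
        anti_aliasing=ratio < 1.0,
        preserve_range=True,
    )
    return image.with_pixels(np.clip(np.round(out), 0, 255).astype(np.uint8))


def compute_footprint_spec(
    rescaled_dims: list[tuple[int, int]], target_scale_px_per_cm: float
) -> FootprintSpec:
    """Elementwise minimum height and width over the rescaled set.

    The minima may come from different frames; taking them elementwise
    guarantees the crop window fits every frame.
    """
    if len(rescaled_dims) == 0:
        raise BenthicReadyError("cannot compute a footprint spec from an empty set")
    heights = [int(h) for h, _ in rescaled_dims]
    widths = [int(w) for _, w in rescaled_dims]
    return FootprintSpec(
        target_scale_px_per_cm=float(target_scale_px_per_cm),
        target_height_px=min(heights),
        target_width_px=min(widths),
    )


def center_crop(image: ImageRecord, target_height_px: int, target_width_px: int) -> ImageRecord:
    """Crop a centered window of exactly the target size (never pads).

    With an odd size difference the smaller margin goes top/left
    (floor offsets), which keeps the operation bit-exactly reproducible.

    Raises
    ------
    GeometryError
        If the target exceeds the image along either axis.
    """
    h, w = image.height_px, image.width_px
    if target_height_px > h or target_width_px > w:
        raise GeometryError(
            f"crop target {target_height_px}x{target_width_px} exceeds image {h}x{w}; "
            "padding is not supported"
        )
    if target_height_px < 1 or target_width_px < 1:
        raise GeometryError("crop target must be at least 1x1")
    top = (h - target_height_px) // 2
    left = (w - target_width_px) // 2
    out = image.pixels[top : top + target_height_px, left : left + target_width_px]
    return image.with_pixels(np.ascontiguousarray(out))


def standardize_set(
    images: list[ImageRecord],
    scales_px_per_cm: list[float],
    target_scale_px_per_cm: float | None = None,
    target_size: tuple[int, int] | None = None,
) -> tuple[list[ImageRecord], FootprintSpec, list[tuple[int, int]]]:
    """Full stage: rescale to the (median or given) scale, crop to common minima.

    Returns the standardized images, the :class:`FootprintSpec` used, and
    the per-image crop offsets (top, left) for the provenance manifest.
    """
    if len(images) != len(scales_px_per_cm):
        raise BenthicReadyError(
            f"{len(images)} images but {len(scales_px_per_cm)} scales"
        )
    if target_scale_px_per_cm is None:
        target_scale_px_per_cm = compute_target_scale(scales_px_per_cm)
    rescaled = [
        rescale_to_scale(img, s, target_scale_px_per_cm)
        for img, s in zip(images, scales_px_per_cm)
    ]
    if target_size is None:
        spec = compute_footprint_spec(
            [(r.height_px, r.width_px) for r in rescaled], target_scale_px_per_cm
        )
    else:
        spec = FootprintSpec(
            target_scale_px_per_cm=float(target_scale_px_per_cm),
            target_height_px=int(target_size[0]),
            target_width_px=int(target_size[1]),
        )
    offsets = [
        ((r.height_px - spec.target_height_px) // 2, (r.width_px - spec.target_width_px) // 2)
        for r in rescaled
    ]
    cropped = [center_crop(r, spec.target_height_px, spec.target_width_px) for r in rescaled]
    return cropped, spec, offsets
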