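"""Color normalization by channel-wise histogram matching to a reference image.

Varying platform altitude leaves every frame with its own overall
brightness and color balance, so frames are not directly comparable.  The
remedy is to pick one well-lit reference frame — the one acquired closest
to the seafloor, i.e. with the highest ground resolution in px/cm — and
remap every other frame's per-channel intensity distribution onto the
reference's.

The remap is the standard monotone CDF-inverse transport on exact 256-bin
histograms: an input intensity ``v`` maps to the lowest reference
intensity ``g`` whose cumulative histogram reaches the input CDF at
``v``.  Monotonicity guarantees rank preservation within each channel.
"""

from __future__ import annotations

import numpy as np

from .errors import BenthicReadyError
from .images import ImageRecord

_LEVELS = 256


def select_reference(images: list[ImageRecord], scales_px_per_cm: list[float]) -> int:
    """Index of the reference frame: maximum px/cm (closest to the seafloor).

    Ground resolution is proportional to the pixel scale, so the frame
    with the largest px/cm carries the most detail per centimeter of
    seabed.  Ties are broken by earliest acquisition time.

    Raises
    ------
    BenthicReadyError
        Empty candidate set or mismatched list lengths.
    """
    if len(images) == 0:
        raise BenthicReadyError("cannot select a reference from an empty image set")
    if len(images) != len(scales_px_per_cm):
        raise BenthicReadyError(
            f"{len(images)} images but {len(scales_px_per_cm)} scale estimates"
        )
    far_future = None

    def key(i: int):
        t = images[i].acquisition_time
        # Unknown times sort after known ones in the tie-break.
        return (-scales_px_per_cm[i], t is None, t or far_future, images[i].filename)

    return min(range(len(images)), key=key)


def _channel_histogram(channel: np.ndarray) -> np.ndarray:
    return np.bincount(channel.ravel(), minlength=_LEVELS).astype(np.float64)


def _matching_lut(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """256-entry lookup table transporting the source histogram onto the reference's.

    ``lut[v]`` is the lowest intensity ``g`` with
    ``cdf_ref[g] >= cdf_src[v]`` — the monotone CDF-inverse map, with ties
    in the reference CDF resolved towards the lowest intensity.
    """
    cdf_src = np.cumsum(_channel_histogram(source))
    cdf_src /= cdf_src[-1]
    cdf_ref = np.cumsum(_channel_histogram(reference))
    cdf_ref /= cdf_ref[-1]
    lut = np.searchsorted(cdf_ref, cdf_src, side="left")
    return np.clip(lut, 0, _LEVELS - 1).astype(np.uint8)


def match_histograms(image: ImageRecord, reference: ImageRecord) -> ImageRecord:
    """Match each RGB channel of ``image`` to the corresponding channel of ``reference``."""
    out = np.empty_like(image.pixels)
    for c in range(3):
        lut = _matching_lut(image.pixels[:, :, c], reference.pixels[:, :, c])
        out[:, :, c] = lut[image.pixels[:, :, c]]
    return image.with_pixels(out)


def normalize_set(
    images: list[ImageRecord],
    scales_px_per_cm: list[float],
    reference_index: int | None = None,
) -> tuple[list[ImageRecord], int]:
    """Match every image to the (selected or given) reference.

    The reference itself passes through the matching too (an identity map
    up to histogram quantization), so all outputs took the same code path.
    Returns the normalized images and the reference index used.
    """
    if reference_index is None:
        reference_index = select_reference(images, scales_px_per_cm)
    if not 0 <= reference_index < len(images):
        raise BenthicReadyError(
            f"reference index {reference_index} out of range for {len(images)} images"
        )
    reference = images[reference_index]
    return [match_histograms(img, reference) for img in images], reference_index
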