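"""Local contrast enhancement via contrast-limited adaptive histogram equalization.

Seafloor frames lit by a strobe concentrate their intensities in a narrow
band, so plain global equalization under-uses the available 0..255 range
in darker or brighter regions.  CLAHE equalizes the histogram within
tiles of the image (with bilinear blending between tiles) so that local
pixel distributions become as uniform as possible and the global image
occupies the full intensity range.  The clip limit bounds how much any
histogram bin may exceed the uniform height, which prevents noise
amplification in flat regions.

Each RGB channel is equalized independently — illumination and water
absorption affect the channels differently, and the downstream
color-normalization stage is also channel-wise.
"""

from __future__ import annotations

import numpy as np
from skimage.exposure import equalize_adapthist

from .errors import GeometryError
from .images import ImageRecord

_NBINS = 256


def equalize_adaptive(
    image: ImageRecord,
    tile_grid: tuple[int, int] = (8, 8),
    clip_limit: float = 2.0,
) -> ImageRecord:
    """Apply CLAHE per channel.

    Parameters
    ----------
    image : ImageRecord
        8-bit RGB input.
    tile_grid : (rows, cols)
        Number of contextual tiles along each axis; the tile size is the
        image size divided by the grid.  Default 8x8.
    clip_limit : float
        Histogram clip limit as a multiple of the uniform histogram height
        (the convention most imaging toolkits use); 1.0 disables
        enhancement beyond redistribution, larger values allow stronger
        contrast.  Default 2.0.

    Raises
    ------
    GeometryError
        If the image has fewer rows/columns than the tile grid (each tile
        must be at least one pixel).
    """
    rows, cols = int(tile_grid[0]), int(tile_grid[1])
    if rows < 1 or cols < 1:
        raise GeometryError(f"tile grid must be positive, got {tile_grid}")
    h, w = image.height_px, image.width_px
    if h < rows or w < cols:
        raise GeometryError(
            f"image {h}x{w} is smaller than the {rows}x{cols} tile grid; "
            "use a smaller grid (e.g. --tiles 2x2)"
        )
    kernel = (max(h // rows, 1), max(w // cols, 1))
    # skimage's clip_limit is the clipped bin height as a fraction of the
    # tile pixel count; dividing by nbins converts from the
    # multiple-of-uniform-height convention used here.
    clip_frac = clip_limit / _NBINS
    out = np.empty_like(image.pixels)
    for c in range(3):
        channel = image.pixels[:, :, c]
        if channel.min() == channel.max():
            # No structure to enhance; equalizing a constant is undefined.
            out[:, :, c] = channel
            continue
        eq = equalize_adapthist(channel, kernel_size=kernel, clip_limit=clip_frac)
        out[:, :, c] = np.floor(eq * 255.0 + 0.5).astype(np.uint8)
    return image.with_pixels(out)
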