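"""8-bit RGB image records and disk I/O.

The pipeline's unit of work is an :class:`ImageRecord`: a ``uint8`` RGB
raster plus the identity that travels with it through every stage (the
original filename and the UTC acquisition time parsed from it).  Only JPG
and PNG are supported; images with an alpha channel or a non-RGB mode are
rejected rather than silently converted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ImageFormatError

SUPPORTED_SUFFIXES = {".jpg", ".jpeg", ".png"}


@dataclass
class ImageRecord:
    """An 8-bit RGB raster with its identity.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(height, width, 3)`` ``uint8`` array, channels R, G, B.
    filename : str
        Basename the image is known by (kept through all stages).
    acquisition_time : datetime.datetime or None
        UTC timestamp at second resolution, usually parsed from the
        filename convention.
    """

    pixels: np.ndarray
    filename: str = ""
    acquisition_time: dt.datetime | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"{self.filename or '<array>'}: expected (H, W, 3) RGB raster, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ImageFormatError(
                f"{self.filename or '<array>'}: expected uint8 intensities, got {px.dtype}"
            )
        self.pixels = px

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    def with_pixels(self, pixels: np.ndarray) -> "ImageRecord":
        """Same identity, new raster (stages return this)."""
        return ImageRecord(pixels=pixels, filename=self.filename, acquisition_time=self.acquisition_time)


def read_image(path: str | Path, acquisition_time: dt.datetime | None = None) -> ImageRecord:
    """Read a JPG/PNG file as an 8-bit RGB :class:`ImageRecord`.

    Raises
    ------
    ImageFormatError
        If the file is not plain 8-bit RGB (alpha, palette, grayscale or
        16-bit images are refused; convert explicitly upstream).
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ImageFormatError(f"{path.name}: unsupported format {path.suffix!r}; use JPG or PNG")
    with Image.open(path) as im:
        if im.mode == "RGBA" or "A" in im.getbands():
            raise ImageFormatError(f"{path.name}: alpha channel not supported; flatten to RGB first")
        if im.mode != "RGB":
            raise ImageFormatError(f"{path.name}: mode {im.mode!r} not supported; expected 8-bit RGB")
        pixels = np.asarray(im, dtype=np.uint8)
    if acquisition_time is None:
        # Parse lazily; a non-conforming name simply leaves the time unset.
        from .metadata import parse_image_filename

        try:
            parsed = parse_image_filename(path.name)
            acquisition_time = parsed.timestamp
        except Exception:
            acquisition_time = None
    return ImageRecord(pixels=pixels, filename=path.name, acquisition_time=acquisition_time)


def write_image(record: ImageRecord, path: str | Path, jpeg_quality: int = 95) -> Path:
    """Write a record to disk; format follows the suffix (PNG is lossless)."""
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ImageFormatError(f"{path.name}: unsupported format {path.suffix!r}; use JPG or PNG")
    im = Image.fromarray(record.pixels, mode="RGB")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        im.save(path, quality=jpeg_quality)
    else:
        im.save(path)
    return path
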