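"""Exception hierarchy for the preprocessing pipeline.

Every error raised on purpose by this package derives from
:class:`BenthicReadyError`, so callers (and the CLI) can catch one type.
"""

from __future__ import annotations


class BenthicReadyError(Exception):
    """Base class for all errors raised by benthic_ready."""


class FilenameParseError(BenthicReadyError):
    """An image filename does not follow the <cruise_station_platform_date_time.JPG> convention."""

    def __init__(self, name: str, token: str, reason: str):
        self.name = name
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse {name!r}: token {token!r}: {reason}")


class MetadataSchemaError(BenthicReadyError):
    """The metadata CSV is missing required columns."""


class MetadataValidationError(BenthicReadyError):
    """One or more metadata rows failed validation.

    ``row_errors`` maps 0-based row index (within the data rows, header
    excluded) to a human-readable message.
    """

    def __init__(self, row_errors: dict[int, str]):
        self.row_errors = dict(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in sorted(self.row_errors.items()))
        super().__init__(f"{len(self.row_errors)} invalid metadata row(s): {lines}")


class ImageFormatError(BenthicReadyError):
    """An image is not 8-bit RGB (e.g. carries an alpha channel or is grayscale)."""


class BatchError(BenthicReadyError):
    """A light-cone batch is unusable (too few images or mismatched shapes)."""


class ScaleUnavailableError(BenthicReadyError):
    """Fewer than two laser points were detected; no scale can be estimated."""


class GeometryError(BenthicReadyError):
    """A geometric operation is infeasible (crop larger than image, dots off-frame, ...)."""


class PipelineError(BenthicReadyError):
    """A pipeline stage failed; carries stage and image context for remediation."""

    def __init__(self, stage: str, image: str | None, message: str, hint: str = ""):
        self.stage = stage
        self.image = image
        self.hint = hint
        where = f"stage {stage!r}" + (f", image {image!r}" if image else "")
        full = f"{where}: {message}"
        if hint:
            full += f" (hint: {hint})"
        super().__init__(full)
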