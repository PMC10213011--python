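"""Filename convention, per-image metadata schema and dataset indexing.

Photo-transect archives name every frame
``<cruise_station_platform_date_time.JPG>`` (e.g.
``SO268_100-1_OFOS_20190304_093510.JPG``) and ship a companion CSV with one
row per image: contract area, water depth, position, UTC acquisition time,
the original scale in cm/pixel from laser-point detection, and a seafloor
substrate class A-D with a classifier confidence score.  This module parses
and reassembles the naming convention, validates CSV rows against that
schema, and summarizes geographic/temporal coverage.

All timestamps are UTC at second resolution; the package never converts
timezones.  Naive :class:`datetime.datetime` objects are used throughout and
documented as UTC.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FilenameParseError, MetadataSchemaError, MetadataValidationError

logger = logging.getLogger(__name__)

SEAFLOOR_CLASSES = ("A", "B", "C", "D")
CONTRACT_AREAS = ("German", "Belgian")

#: Default CSV column names.  The published archives do not pin exact header
#: strings, so these are descriptive defaults; remap via the ``column_map``
#: argument of :func:`read_metadata_table`.
DEFAULT_COLUMNS = {
    "image_name": "image_name",
    "contract_area": "contract_area",
    "depth_m": "depth_m",
    "latitude": "latitude",
    "longitude": "longitude",
    "acquired_at": "acquired_at",
    "original_scale_cm_per_px": "original_scale_cm_per_px",
    "seafloor_class": "seafloor_class",
    "class_score": "class_score",
}


@dataclass(frozen=True)
class ParsedFilename:
    """The five fields of the filename convention plus the literal extension."""

    cruise: str
    station: str
    platform: str
    date: dt.date
    time: dt.time
    extension: str = ".JPG"

    @property
    def timestamp(self) -> dt.datetime:
        """UTC acquisition time combined from the date and time tokens."""
        return dt.datetime.combine(self.date, self.time)


def parse_image_filename(name: str) -> ParsedFilename:
    """Parse ``<cruise_station_platform_date_time.JPG>``.

    The name is split on underscores only; the last two tokens are the date
    (``YYYYMMDD``) and time (``HHMMSS``), the token before them the platform,
    the first token the cruise, and everything in between the station (which
    may itself contain hyphens or underscores, e.g. ``100-1``).

    Raises
    ------
    FilenameParseError
        Wrong token count, or a date/time token that does not parse.
    """
    if not name.lower().endswith((".jpg", ".png")):
        raise FilenameParseError(name, name, "expected a .JPG/.jpg (or .png) extension")
    dot = name.rfind(".")
    stem, extension = name[:dot], name[dot:]
    tokens = stem.split("_")
    if len(tokens) < 5:
        raise FilenameParseError(
            name, stem, f"expected >=5 underscore-separated tokens, got {len(tokens)}"
        )
    cruise, platform, date_tok, time_tok = tokens[0], tokens[-3], tokens[-2], tokens[-1]
    station = "_".join(tokens[1:-3])
    try:
        date = dt.datetime.strptime(date_tok, "%Y%m%d").date()
    except ValueError as exc:
        raise FilenameParseError(name, date_tok, f"bad date token: {exc}") from None
    try:
        time = dt.datetime.strptime(time_tok, "%H%M%S").time()
    except ValueError as exc:
        raise FilenameParseError(name, time_tok, f"bad time token: {exc}") from None
    return ParsedFilename(cruise, station, platform, date, time, extension)


def assemble_image_filename(parsed: ParsedFilename) -> str:
    """Inverse of :func:`parse_image_filename`; round-trips well-formed names exactly."""
    return (
        f"{parsed.cruise}_{parsed.station}_{parsed.platform}_"
        f"{parsed.date:%Y%m%d}_{parsed.time:%H%M%S}{parsed.extension}"
    )


@dataclass
class MetadataRecord:
    """One validated row of the per-image metadata table."""

    image_name: str
    contract_area: str
    depth_m: float
    latitude: float
    longitude: float
    acquired_at: dt.datetime
    original_scale_cm_per_px: float
    seafloor_class: str
    class_score: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems = []
        if self.contract_area not in CONTRACT_AREAS:
            problems.append(
                f"contract_area {self.contract_area!r} not in {sorted(CONTRACT_AREAS)}"
            )
        if not np.isfinite(self.depth_m) or self.depth_m < 0:
            problems.append(f"depth_m {self.depth_m!r} must be a nonnegative real (meters)")
        if self.seafloor_class not in SEAFLOOR_CLASSES:
            problems.append(
                f"seafloor_class {self.seafloor_class!r} not one of the allowed classes "
                f"{list(SEAFLOOR_CLASSES)}"
            )
        if not (np.isfinite(self.original_scale_cm_per_px) and self.original_scale_cm_per_px > 0):
            problems.append(
                f"original_scale_cm_per_px {self.original_scale_cm_per_px!r} must be > 0"
            )
        if not (np.isfinite(self.class_score) and 0.0 <= self.class_score <= 1.0):
            problems.append(f"class_score {self.class_score!r} must be in [0, 1]")
        if self.acquired_at.microsecond != 0:
            # Second resolution is part of the schema; truncate silently would
            # break the round-trip contract, so refuse.
            problems.append(f"acquired_at {self.acquired_at!r} must have second resolution")
        if problems:
            raise MetadataValidationError({0: "; ".join(problems)})

    @property
    def scale_px_per_cm(self) -> float:
        """Reciprocal of the archived cm/pixel value."""
        return 1.0 / self.original_scale_cm_per_px


@dataclass
class CoverageSummary:
    median_latitude: float
    median_longitude: float
    south_bound_latitude: float
    north_bound_latitude: float
    west_bound_longitude: float
    east_bound_longitude: float
    time_start: dt.datetime
    time_end: dt.datetime


@dataclass
class DatasetIndex:
    """Metadata records kept sorted by acquisition time (ties by image name)."""

    records: list[MetadataRecord]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.acquired_at, r.image_name))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def summarize_coverage(index: DatasetIndex) -> CoverageSummary:
    """Median position, bounding box and time span over all records.

    Medians over an even count are the arithmetic mean of the two central
    values (numpy's convention).
    """
    if len(index) == 0:
        raise MetadataValidationError({0: "cannot summarize an empty dataset index"})
    lats = np.array([r.latitude for r in index.records], dtype=float)
    lons = np.array([r.longitude for r in index.records], dtype=float)
    times = [r.acquired_at for r in index.records]
    return CoverageSummary(
        median_latitude=float(np.median(lats)),
        median_longitude=float(np.median(lons)),
        south_bound_latitude=float(lats.min()),
        north_bound_latitude=float(lats.max()),
        west_bound_longitude=float(lons.min()),
        east_bound_longitude=float(lons.max()),
        time_start=min(times),
        time_end=max(times),
    )


def _parse_timestamp(value) -> dt.datetime:
    if isinstance(value, dt.datetime):
        ts = value
    else:
        ts = pd.Timestamp(str(value)).to_pydatetime()
    if ts.tzinfo is not None:
        # Schema is UTC by definition; strip an explicit UTC marker, reject others.
        if ts.utcoffset() != dt.timedelta(0):
            raise ValueError(f"timestamp {value!r} carries a non-UTC offset")
        ts = ts.replace(tzinfo=None)
    return ts


def read_metadata_table(
    path,
    column_map: dict[str, str] | None = None,
    skip_bad: bool = False,
) -> DatasetIndex:
    """Read and validate the metadata CSV into a :class:`DatasetIndex`.

    Parameters
    ----------
    path : path-like
        UTF-8, comma-separated CSV with a header row.
    column_map : dict, optional
        Maps schema field names (keys of :data:`DEFAULT_COLUMNS`) to the
        actual header names in the file.  Unmapped extra columns are carried
        along untouched in each record's ``extras``.
    skip_bad : bool
        If true, rows that fail validation are dropped (and logged) instead
        of aborting the read.  Default: collect every row error and raise.

    Raises
    ------
    MetadataSchemaError
        A required column is absent from the header.
    MetadataValidationError
        One or more rows failed validation (unless ``skip_bad``).
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in columns.values() if v not in df.columns]
    if missing:
        raise MetadataSchemaError(
            f"metadata CSV is missing required column(s) {missing}; present: {list(df.columns)}"
        )
    extra_cols = [c for c in df.columns if c not in set(columns.values())]
    if len(df) == 0:
        logger.warning("metadata CSV %s has a header but no rows", path)
        return DatasetIndex(records=[])

    records: list[MetadataRecord] = []
    row_errors: dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            rec = MetadataRecord(
                image_name=row[columns["image_name"]],
                contract_area=row[columns["contract_area"]],
                depth_m=float(row[columns["depth_m"]]),
                latitude=float(row[columns["latitude"]]),
                longitude=float(row[columns["longitude"]]),
                acquired_at=_parse_timestamp(row[columns["acquired_at"]]),
                original_scale_cm_per_px=float(row[columns["original_scale_cm_per_px"]]),
                seafloor_class=row[columns["seafloor_class"]],
                class_score=float(row[columns["class_score"]]),
                extras={c: row[c] for c in extra_cols},
            )
        except MetadataValidationError as exc:
            row_errors[i] = exc.row_errors.get(0, str(exc))
        except (ValueError, KeyError) as exc:
            row_errors[i] = str(exc)
        else:
            records.append(rec)
    if row_errors and not skip_bad:
        raise MetadataValidationError(row_errors)
    if row_errors:
        logger.warning("skipped %d invalid metadata row(s)", len(row_errors))
    return DatasetIndex(records=records)


def write_metadata_table(index: DatasetIndex, path, column_map: dict[str, str] | None = None):
    """Write a :class:`DatasetIndex` back to CSV (inverse of :func:`read_metadata_table`)."""
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    rows = []
    for r in index.records:
        row = {
            columns["image_name"]: r.image_name,
            columns["contract_area"]: r.contract_area,
            columns["depth_m"]: repr(r.depth_m),
            columns["latitude"]: repr(r.latitude),
            columns["longitude"]: repr(r.longitude),
            columns["acquired_at"]: r.acquired_at.isoformat(sep="T"),
            columns["original_scale_cm_per_px"]: repr(r.original_scale_cm_per_px),
            columns["seafloor_class"]: r.seafloor_class,
            columns["class_score"]: repr(r.class_score),
        }
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
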