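"""Filename convention, metadata CSV schema and coverage summaries."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthic_ready.errors import (
    FilenameParseError,
    MetadataSchemaError,
    MetadataValidationError,
)
from benthic_ready.metadata import (
    DatasetIndex,
    MetadataRecord,
    assemble_image_filename,
    parse_image_filename,
    read_metadata_table,
    summarize_coverage,
    write_metadata_table,
)


def make_record(i: int = 0, **overrides) -> MetadataRecord:
    base = dict(
        image_name=f"SO268_100-1_OFOS_20190304_{93510 + i:06d}.JPG",
        contract_area="German",
        depth_m=4250.0,
        latitude=12.6 + 0.01 * i,
        longitude=-119.97 - 0.01 * i,
        acquired_at=dt.datetime(2019, 3, 4, 9, 35, 10) + dt.timedelta(seconds=10 * i),
        original_scale_cm_per_px=0.05,
        seafloor_class="B",
        class_score=0.9,
    )
    base.update(overrides)
    return MetadataRecord(**base)


class TestFilenameConvention:
    def test_parses_the_documented_example(self):
        p = parse_image_filename("SO268_100-1_OFOS_20190304_093510.JPG")
        assert (p.cruise, p.station, p.platform) == ("SO268", "100-1", "OFOS")
        assert p.timestamp == dt.datetime(2019, 3, 4, 9, 35, 10)

    def test_round_trip_is_identity(self):
        name = "SO268_100-1_OFOS_20190304_093510.JPG"
        assert assemble_image_filename(parse_image_filename(name)) == name

    @pytest.mark.parametrize(
        "bad",
        [
            "badname.JPG",  # too few tokens
            "SO268_100-1_OFOS_20191341_093510.JPG",  # month 13, day 41
            "SO268_100-1_OFOS_20190304_935Z10.JPG",  # unparseable time
            "SO268_100-1_OFOS_20190304_093510.tif",  # wrong extension
        ],
    )
    def test_malformed_names_raise_structured_errors(self, bad):
        with pytest.raises(FilenameParseError):
            parse_image_filename(bad)

    @settings(max_examples=100, deadline=None)
    @given(
        cruise=st.from_regex(r"[A-Z]{2}[0-9]{3}", fullmatch=True),
        station=st.from_regex(r"[0-9]{1,3}(-[0-9]{1,2})?", fullmatch=True),
        platform=st.from_regex(r"[A-Z]{3,5}", fullmatch=True),
        ts=st.datetimes(
            min_value=dt.datetime(2019, 1, 1), max_value=dt.datetime(2020, 1, 1)
        ).map(lambda t: t.replace(microsecond=0)),
    )
    def test_parse_assemble_bijection_on_wellformed_names(self, cruise, station, platform, ts):
        name = f"{cruise}_{station}_{platform}_{ts:%Y%m%d}_{ts:%H%M%S}.JPG"
        parsed = parse_image_filename(name)
        assert assemble_image_filename(parsed) == name
        assert parsed.timestamp == ts


class TestMetadataTable:
    def test_read_sorts_by_acquisition_time(self, tmp_path):
        index = DatasetIndex(records=[make_record(2), make_record(0), make_record(1)])
        path = tmp_path / "meta.csv"
        write_metadata_table(index, path)
        back = read_metadata_table(path)
        assert len(back) == 3
        times = [r.acquired_at for r in back]
        assert times == sorted(times)

    def test_round_trip_preserves_values(self, tmp_path):
        recs = [make_record(i, class_score=0.25 + 0.1 * i) for i in range(4)]
        path = tmp_path / "meta.csv"
        write_metadata_table(DatasetIndex(records=recs), path)
        back = read_metadata_table(path)
        for a, b in zip(recs, back):
            assert a.image_name == b.image_name
            assert a.seafloor_class == b.seafloor_class
            assert a.acquired_at == b.acquired_at
            for fieldname in ("depth_m", "latitude", "longitude",
                              "original_scale_cm_per_px", "class_score"):
                assert getattr(a, fieldname) == pytest.approx(getattr(b, fieldname), abs=1e-9)

    def test_unknown_seafloor_class_reports_allowed_set(self, tmp_path):
        path = tmp_path / "meta.csv"
        write_metadata_table(DatasetIndex(records=[make_record(0)]), path)
        text = path.read_text().replace(",B,", ",E,")
        path.write_text(text)
        with pytest.raises(MetadataValidationError) as err:
            read_metadata_table(path)
        assert "A" in str(err.value) and "D" in str(err.value)

    def test_skip_bad_drops_only_offending_rows(self, tmp_path):
        path = tmp_path / "meta.csv"
        write_metadata_table(DatasetIndex(records=[make_record(0), make_record(1)]), path)
        path.write_text(path.read_text().replace(",B,", ",E,", 1))
        back = read_metadata_table(path, skip_bad=True)
        assert len(back) == 1

    def test_missing_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("image_name,latitude\nfoo.JPG,12.5\n")
        with pytest.raises(MetadataSchemaError):
            read_metadata_table(path)

    def test_header_only_csv_yields_empty_index(self, tmp_path):
        path = tmp_path / "meta.csv"
        write_metadata_table(DatasetIndex(records=[make_record(0)]), path)
        lines = path.read_text().splitlines()
        path.write_text(lines[0] + "\n")
        assert len(read_metadata_table(path)) == 0

    def test_extra_columns_are_preserved(self, tmp_path):
        rec = make_record(0, extras={"note": "plume"})
        path = tmp_path / "meta.csv"
        write_metadata_table(DatasetIndex(records=[rec]), path)
        back = read_metadata_table(path)
        assert back.records[0].extras["note"] == "plume"

    def test_column_map_renames_headers(self, tmp_path):
        path = tmp_path / "meta.csv"
        cmap = {"image_name": "File name"}
        write_metadata_table(DatasetIndex(records=[make_record(0)]), path, column_map=cmap)
        back = read_metadata_table(path, column_map=cmap)
        assert back.records[0].image_name.endswith(".JPG")


class TestCoverage:
    def test_median_of_three_latitudes(self):
        recs = [make_record(i, latitude=float(v)) for i, v in enumerate([1, 2, 3])]
        cov = summarize_coverage(DatasetIndex(records=recs))
        assert cov.median_latitude == 2.0

    def test_single_record_degenerate_bounds(self):
        rec = make_record(0)
        cov = summarize_coverage(DatasetIndex(records=[rec]))
        assert cov.median_latitude == rec.latitude
        assert cov.south_bound_latitude == cov.north_bound_latitude == rec.latitude
        assert cov.time_start == cov.time_end == rec.acquired_at

    def test_empty_index_errors(self):
        with pytest.raises(MetadataValidationError):
            summarize_coverage(DatasetIndex(records=[]))

    def test_median_invariant_under_permutation(self, rng):
        lats = rng.uniform(11.8, 14.2, size=9)
        recs = [make_record(i, latitude=float(v)) for i, v in enumerate(lats)]
        cov1 = summarize_coverage(DatasetIndex(records=recs))
        perm = [recs[i] for i in rng.permutation(9)]
        cov2 = summarize_coverage(DatasetIndex(records=perm))
        assert cov1.median_latitude == cov2.median_latitude == np.median(lats)
        assert cov1.median_longitude == cov2.median_longitude
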