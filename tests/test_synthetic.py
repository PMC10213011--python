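"""Synthetic scene generator: determinism, vignette, scale model, laser geometry."""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pytest

from benthic_ready.errors import GeometryError
from benthic_ready.metadata import parse_image_filename
from benthic_ready.synthetic import (
    SceneParams,
    generate_scene,
    generate_transect,
    vignette_map,
)
from conftest import SMALL


def patch_means(px: np.ndarray, frac: float = 0.05):
    """Mean intensity of the four corner patches and the central patch.

    Each patch covers ``frac`` of the image area.
    """
    h, w = px.shape[:2]
    ph, pw = int(h * np.sqrt(frac)), int(w * np.sqrt(frac))
    corners = np.mean(
        [px[:ph, :pw].mean(), px[:ph, -pw:].mean(), px[-ph:, :pw].mean(), px[-ph:, -pw:].mean()]
    )
    cy, cx = h // 2, w // 2
    center = px[cy - ph // 2 : cy + ph // 2, cx - pw // 2 : cx + pw // 2].mean()
    return corners, center


class TestSceneRendering:
    def test_identical_params_render_bit_identical_rasters(self, small_params):
        a, _ = generate_scene(small_params)
        b, _ = generate_scene(small_params)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seeds_render_different_rasters(self, small_params):
        a, _ = generate_scene(small_params)
        b, _ = generate_scene(dataclasses.replace(small_params, seed=small_params.seed + 1))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_no_degradations_means_flat_illumination(self):
        p = SceneParams(
            seed=3, **SMALL,
            vignette_strength=0.0, color_cast=(1.0, 1.0, 1.0), noise_sd=0.0,
            nodule_density_per_m2=0.0,
        )
        rec, _ = generate_scene(p)
        corners, center = patch_means(rec.pixels.astype(float))
        # Only the smooth texture differs between patches.
        assert abs(corners - center) < 3.0

    def test_strong_vignette_darkens_corners(self):
        p = SceneParams(seed=3, **SMALL, vignette_strength=0.8, nodule_density_per_m2=0.0)
        rec, _ = generate_scene(p)
        corners, center = patch_means(rec.pixels.astype(float))
        assert corners < 0.6 * center

    def test_doubling_altitude_halves_scale_and_laser_separation(self):
        p1 = SceneParams(seed=5, **SMALL, altitude_m=1.0)
        p2 = dataclasses.replace(p1, altitude_m=2.0)
        rec1, t1 = generate_scene(p1)
        rec2, t2 = generate_scene(p2)
        assert t2.true_scale_px_per_cm == pytest.approx(t1.true_scale_px_per_cm / 2)
        d1 = np.hypot(*(t1.laser_points_px[0] - t1.laser_points_px[1]))
        d2 = np.hypot(*(t2.laser_points_px[0] - t2.laser_points_px[1]))
        assert d2 == pytest.approx(d1 / 2, abs=1.0)

    def test_ground_truth_laser_geometry_matches_scale(self, small_scene):
        _, truth = small_scene
        pts = truth.laser_points_px
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.hypot(*(pts[i] - pts[j]))
                assert d / truth.laser_separation_cm == pytest.approx(
                    truth.true_scale_px_per_cm, abs=1.0 / truth.laser_separation_cm
                )

    def test_laser_dots_are_stamped_pure_red(self, small_scene):
        rec, truth = small_scene
        for row, col in truth.laser_points_px:
            r, c = round(row), round(col)
            assert rec.pixels[r, c, 0] >= 250
            assert rec.pixels[r, c, 1] <= 30 and rec.pixels[r, c, 2] <= 30

    def test_oversized_laser_triangle_raises(self):
        p = SceneParams(seed=1, **SMALL, laser_separation_cm=100.0, altitude_m=0.5)
        with pytest.raises(GeometryError):
            generate_scene(p)

    def test_vignette_map_monotone_in_radius(self):
        vmap = vignette_map(101, 101, strength=0.7, radius_frac=0.9)
        center_row = vmap[50, 50:]
        assert np.all(np.diff(center_row) <= 1e-12)
        assert vmap.max() == pytest.approx(1.0, abs=1e-6)


class TestTransect:
    def test_single_frame_transect(self):
        scenes = generate_transect(1, seed=9, params=SceneParams(**SMALL))
        assert len(scenes) == 1
        rec, truth = scenes[0]
        assert 1.0 <= SceneParams(**SMALL).base_scale_px_per_cm_at_1m / truth.true_scale_px_per_cm <= 3.0

    def test_fixed_seed_reproduces_whole_transect(self):
        a = generate_transect(5, seed=21, params=SceneParams(**SMALL))
        b = generate_transect(5, seed=21, params=SceneParams(**SMALL))
        for (ra, ta), (rb, tb) in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)
            assert ra.filename == rb.filename
            assert ta.true_scale_px_per_cm == tb.true_scale_px_per_cm

    def test_timestamps_spaced_ten_seconds_and_filenames_parse(self, small_transect):
        times = [rec.acquisition_time for rec, _ in small_transect]
        deltas = {(b - a).total_seconds() for a, b in zip(times, times[1:])}
        assert deltas == {10.0}
        for rec, _ in small_transect:
            assert parse_image_filename(rec.filename).timestamp == rec.acquisition_time

    def test_altitude_range_spans_twofold_scale_ratio(self):
        scenes = generate_transect(100, seed=2, altitude_range=(1.0, 3.0),
                                   params=SceneParams(**SMALL))
        scales = [t.true_scale_px_per_cm for _, t in scenes]
        assert max(scales) / min(scales) >= 2.0
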