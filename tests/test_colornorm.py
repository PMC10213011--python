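"""Color normalization: reference selection and channel-wise histogram matching."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from skimage.exposure import match_histograms as skimage_match

from benthic_ready.colornorm import match_histograms, normalize_set, select_reference
from benthic_ready.errors import BenthicReadyError
from benthic_ready.images import ImageRecord
from benthic_ready.validation import median_intensity


def img_of(array, name="img", t=None) -> ImageRecord:
    return ImageRecord(np.asarray(array, np.uint8), filename=name, acquisition_time=t)


def brute_force_match(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Independent oracle: per-value CDF-inverse search with explicit loops."""
    out = np.empty_like(source)
    n_src = source.size
    n_ref = reference.size
    src_counts = [int(np.sum(source == v)) for v in range(256)]
    ref_counts = [int(np.sum(reference == v)) for v in range(256)]
    for v in range(256):
        cdf_v = sum(src_counts[: v + 1]) / n_src
        running = 0
        g_star = 255
        for g in range(256):
            running += ref_counts[g]
            if running / n_ref >= cdf_v - 1e-12:
                g_star = g
                break
        out[source == v] = g_star
    return out


class TestReferenceSelection:
    def test_picks_maximum_scale(self):
        imgs = [img_of(np.zeros((2, 2, 3)), name=n) for n in "abc"]
        assert select_reference(imgs, [18.2, 21.5, 25.0]) == 2

    def test_single_image_is_its_own_reference(self):
        assert select_reference([img_of(np.zeros((2, 2, 3)))], [5.0]) == 0

    def test_tie_broken_by_earliest_acquisition(self):
        t0 = dt.datetime(2019, 3, 4, 9, 35, 10)
        imgs = [
            img_of(np.zeros((2, 2, 3)), name="late", t=t0 + dt.timedelta(seconds=10)),
            img_of(np.zeros((2, 2, 3)), name="early", t=t0),
        ]
        assert select_reference(imgs, [25.0, 25.0]) == 1

    def test_empty_set_errors(self):
        with pytest.raises(BenthicReadyError):
            select_reference([], [])


class TestHistogramMatching:
    def test_identity_when_matched_to_itself(self, small_scene):
        rec, _ = small_scene
        out = match_histograms(rec, rec)
        assert np.array_equal(out.pixels, rec.pixels)

    def test_constant_to_constant_is_point_mass_transport(self):
        src = img_of(np.full((8, 8, 3), 64))
        ref = img_of(np.full((8, 8, 3), 200))
        out = match_histograms(src, ref)
        assert np.all(out.pixels == 200)

    def test_agrees_with_brute_force_cdf_inverse_oracle(self, rng):
        src = img_of(rng.integers(0, 256, (16, 16, 3)))
        ref = img_of(rng.integers(0, 256, (16, 16, 3)))
        out = match_histograms(src, ref)
        for c in range(3):
            expected = brute_force_match(src.pixels[:, :, c], ref.pixels[:, :, c])
            assert np.array_equal(out.pixels[:, :, c], expected)

    def test_close_to_skimage_reference_implementation(self, rng):
        """Independent library cross-check; small quantization slack allowed."""
        src = img_of(rng.integers(30, 220, (32, 32, 3)))
        ref = img_of(rng.integers(0, 256, (32, 32, 3)))
        ours = match_histograms(src, ref).pixels.astype(int)
        theirs = np.rint(skimage_match(src.pixels, ref.pixels, channel_axis=-1)).astype(int)
        assert np.abs(ours - theirs).max() <= 2

    def test_ks_distance_small_when_no_heavy_ties(self, rng):
        """Each level appears once in the source, so the CDF transport is near-exact."""
        for c_seed in range(3):
            levels = rng.permutation(256).reshape(16, 16)
            src = img_of(np.stack([levels] * 3, axis=-1))
            ref = img_of(rng.integers(0, 256, (16, 16, 3)))
            out = match_histograms(src, ref)
            for c in range(3):
                h_out = np.bincount(out.pixels[:, :, c].ravel(), minlength=256) / 256
                h_ref = np.bincount(ref.pixels[:, :, c].ravel(), minlength=256) / 256
                ks = np.abs(np.cumsum(h_out) - np.cumsum(h_ref)).max()
                assert ks < 2 / 256

    def test_monotone_rank_preservation(self, rng):
        src = img_of(rng.integers(0, 256, (16, 16, 3)))
        ref = img_of(rng.integers(0, 256, (16, 16, 3)))
        out = match_histograms(src, ref)
        for c in range(3):
            s = src.pixels[:, :, c].ravel().astype(int)
            o = out.pixels[:, :, c].ravel().astype(int)
            # s[p] < s[q] implies o[p] <= o[q]: the per-level map is nondecreasing
            lut = {}
            for sv, ov in zip(s, o):
                lut.setdefault(sv, ov)
            keys = sorted(lut)
            assert all(lut[a] <= lut[b] for a, b in zip(keys, keys[1:]))


def test_brightness_harmonized_across_heterogeneous_casts(small_transect):
    """Across-image variance of per-channel median intensity collapses after matching."""
    imgs = [rec for rec, _ in small_transect]
    scales = [t.true_scale_px_per_cm for _, t in small_transect]
    normalized, _ = normalize_set(imgs, scales)
    before = np.array([median_intensity(i).as_tuple() for i in imgs]).var(axis=0)
    after = np.array([median_intensity(i).as_tuple() for i in normalized]).var(axis=0)
    assert np.all(after < 0.05 * before)
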