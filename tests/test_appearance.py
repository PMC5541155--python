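"""Patch extraction, appearance-pyramid assembly, trimming, reconstruction."""

import numpy as np
import pytest
from scipy import ndimage

import dap
from dap.appearance import (
    AppearancePyramid,
    Patch,
    ScaleIndexSets,
    Shape,
    devectorize,
    extract_appearance_pyramid,
    extract_patch,
    reconstruct_appearance,
    trim_scale_sets,
    vectorize,
)
from dap.pyramids import build_gaussian_pyramid, build_spectral_windows, build_wavelet_pyramid


@pytest.fixture()
def ramp_pyramid():
    r, c = np.mgrid[0:64, 0:64]
    return build_gaussian_pyramid(2.0 * r + 0.5 * c, L=2)


class TestExtractPatch:
    def test_constant_image(self):
        pyr = build_gaussian_pyramid(np.full((64, 64), 1.5), L=2)
        pt = extract_patch(pyr, np.array([20.3, 40.7]), 2, 9)
        assert np.allclose(pt.pixels, 1.5)

    def test_integer_center_is_raw_window(self, ramp_pyramid):
        img = ramp_pyramid.levels[0]
        pt = extract_patch(ramp_pyramid, np.array([20.0, 30.0]), 1, 5)
        assert np.array_equal(pt.pixels, img[18:23, 28:33])

    def test_half_pixel_shift_on_ramp_is_midpoint(self, ramp_pyramid):
        # bilinear sampling of a linear ramp at +0.5 rows averages neighbours
        a = extract_patch(ramp_pyramid, np.array([20.0, 30.0]), 1, 5).pixels
        b = extract_patch(ramp_pyramid, np.array([21.0, 30.0]), 1, 5).pixels
        mid = extract_patch(ramp_pyramid, np.array([20.5, 30.0]), 1, 5).pixels
        assert np.allclose(mid, (a + b) / 2)

    def test_out_of_bounds_replicates_edge(self):
        pyr = build_gaussian_pyramid(np.arange(64.0)[:, None] * np.ones((1, 64)), L=1)
        pt = extract_patch(pyr, np.array([0.0, 32.0]), 1, 7)
        assert np.allclose(pt.pixels[0], pt.pixels[1])  # rows above edge clamp

    def test_even_patch_size_rejected(self, ramp_pyramid):
        with pytest.raises(ValueError):
            extract_patch(ramp_pyramid, np.array([10.0, 10.0]), 1, 8)

    def test_translation_covariance(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 1.0)
        pyr = build_gaussian_pyramid(img, L=1)
        shifted = np.roll(img, (3, -2), axis=(0, 1))
        pyr2 = build_gaussian_pyramid(shifted, L=1)
        x = np.array([30.0, 30.0])
        a = extract_patch(pyr, x, 1, 9).pixels
        b = extract_patch(pyr2, x + np.array([3.0, -2.0]), 1, 9).pixels
        assert np.allclose(a, b)


class TestAppearancePyramidVectorization:
    def test_single_landmark_matches_extract_patch(self):
        pyr = build_gaussian_pyramid(np.random.default_rng(1).normal(size=(64, 64)), L=2)
        s = Shape(np.array([[30.0, 30.0]]))
        K = ScaleIndexSets([(1,)])
        ap = extract_appearance_pyramid(pyr, s, K, 9)
        direct = extract_patch(pyr, s.points[0], 1, 9)
        assert np.array_equal(ap.patches[0].pixels, direct.pixels)

    def test_coincident_landmarks_duplicate_blocks(self):
        pyr = build_gaussian_pyramid(np.random.default_rng(2).normal(size=(64, 64)), L=2)
        s = Shape(np.array([[30.0, 30.0], [30.0, 30.0]]))
        ap = extract_appearance_pyramid(pyr, s, ScaleIndexSets.full(2, 2), 9)
        v = vectorize(ap)
        half = v.size // 2
        assert np.array_equal(v[:half], v[half:])

    def test_vectorize_devectorize_bijection(self):
        K = ScaleIndexSets([(1, 2), (1,), (1, 2)])
        rng = np.random.default_rng(3)
        patches = [
            Patch(pixels=rng.normal(size=(5, 5)), landmark_index=n, level=l)
            for n, l in K.index_pairs()
        ]
        ap = AppearancePyramid(patches=patches, K=K, patch_size=5)
        v = vectorize(ap)
        assert v.size == K.n_patches() * 25
        ap2 = devectorize(v, K, 5)
        for a, b in zip(ap.patches, ap2.patches):
            assert np.array_equal(a.pixels, b.pixels)

    def test_single_pixel_difference_localized(self):
        K = ScaleIndexSets([(1,)])
        ap1 = devectorize(np.ones(9), K, 3)
        v2 = np.ones(9)
        v2[4] += 1.0
        ap2 = devectorize(v2, K, 3)
        assert np.sum(vectorize(ap1) != vectorize(ap2)) == 1

    def test_extraction_deterministic_bitwise(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(64, 64))
        pyr = build_gaussian_pyramid(img, L=3)
        s = Shape(rng.uniform(10, 50, size=(5, 2)))
        K = ScaleIndexSets.full(5, 3)
        v1 = vectorize(extract_appearance_pyramid(pyr, s, K, 9))
        v2 = vectorize(extract_appearance_pyramid(pyr, s, K, 9))
        assert np.array_equal(v1, v2)


def _training_aps(n_samples=3, N=4, L=3, p=9, seed=0, coincide=False):
    rng = np.random.default_rng(seed)
    aps = []
    pts = rng.uniform(20, 44, size=(N, 2))
    if coincide:
        pts[1] = pts[0]
    for _ in range(n_samples):
        img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 1.0)
        pyr = build_gaussian_pyramid(img, L=L)
        aps.append(extract_appearance_pyramid(pyr, Shape(pts), ScaleIndexSets.full(N, L), p))
    return aps


class TestTrimScaleSets:
    def test_zero_threshold_trims_nothing(self):
        K = trim_scale_sets(_training_aps(), threshold=0.0)
        assert all(k == (1, 2, 3) for k in K.sets)

    def test_infinite_threshold_trims_everything_trimmable(self):
        K = trim_scale_sets(_training_aps(), threshold=np.inf)
        assert all(k == (1,) for k in K.sets)

    def test_level1_never_removed(self):
        K = trim_scale_sets(_training_aps(), threshold=1e9)
        assert all(1 in k for k in K.sets)

    def test_coincident_identical_patches_removed_first(self):
        aps = _training_aps(coincide=True)
        # find the smallest threshold that removes exactly one patch
        K = trim_scale_sets(aps, threshold=1e-9)
        removed = [
            (n, l)
            for n in range(4)
            for l in (2, 3)
            if l not in K.sets[n]
        ]
        assert removed and all(n in (0, 1) for n, _ in removed)

    def test_order_independent(self):
        aps = _training_aps(n_samples=4, seed=5)
        K1 = trim_scale_sets(aps, threshold=0.5)
        K2 = trim_scale_sets(aps[::-1], threshold=0.5)
        assert K1.sets == K2.sets

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            trim_scale_sets([], threshold=1.0)


class TestReconstruction:
    def test_zero_patches_give_zero_image(self):
        K = ScaleIndexSets([(1,)])
        ap = devectorize(np.zeros(81), K, 9)
        s = Shape(np.array([[32.0, 32.0]]))
        rec = reconstruct_appearance(ap, s, "gaussian", base_shape=(64, 64))
        assert np.allclose(rec, 0.0)

    def test_overlapping_constant_patches_average_without_doubling(self):
        K = ScaleIndexSets([(1,), (1,)])
        ap = devectorize(np.full(2 * 81, 2.5), K, 9)
        s = Shape(np.array([[32.0, 32.0], [35.0, 32.0]]))
        rec = reconstruct_appearance(ap, s, "gaussian", base_shape=(64, 64))
        covered = rec != 0
        assert np.allclose(rec[covered], 2.5)

    def test_wavelet_compact_support_round_trip(self):
        # content wholly inside every patch footprint: padding + synthesis
        # recovers the original inside the footprint
        size, p = 128, 49
        img = np.zeros((size, size))
        img[size // 2, size // 2] = 1.0
        img = ndimage.gaussian_filter(img, 2.0)
        ws = build_spectral_windows((size, size), 3)
        pyr = build_wavelet_pyramid(img, ws)
        s = Shape(np.array([[size / 2, size / 2]]))
        ap = extract_appearance_pyramid(pyr, s, ScaleIndexSets.full(1, 3), p)
        rec = reconstruct_appearance(ap, s, "wavelet", windows=ws)
        h = p // 2
        sl = slice(size // 2 - h, size // 2 + h + 1)
        err = np.linalg.norm(rec[sl, sl] - img[sl, sl]) / np.linalg.norm(img[sl, sl])
        assert err < 1e-3

    def test_incomplete_ap_rejected(self):
        K = ScaleIndexSets([(1,), (1,)])
        with pytest.raises(ValueError):
            AppearancePyramid(
                patches=[Patch(np.zeros((3, 3)), 0, 1)], K=K, patch_size=3
            )
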