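"""Localization and cropping: every operator against an independent oracle."""

import numpy as np
import pytest

from conftest import make_ellipse_image
from zfscreen import preprocess
from zfscreen.preprocess import (
    CropParams,
    LarvaRegion,
    NoObjectError,
    binarize,
    dilate,
    largest_component,
    locate_and_crop,
    locate_region,
    square_crop,
    variance_filter,
)


# ----------------------------------------------------------------- oracles

def brute_force_variance(gray, radius):
    """Nested-loop population variance over full windows; border zeroed."""
    H, W = gray.shape
    out = np.zeros((H, W))
    for r in range(radius, H - radius):
        for c in range(radius, W - radius):
            win = gray[r - radius : r + radius + 1, c - radius : c + radius + 1]
            out[r, c] = win.var()
    return out


def brute_force_dilate(mask, iterations):
    """Repeated union of the 8 shifted copies plus the original."""
    out = mask.copy()
    for _ in range(iterations):
        prev = out
        out = prev.copy()
        H, W = mask.shape
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                src = prev[
                    max(0, -dr) : H - max(0, dr), max(0, -dc) : W - max(0, dc)
                ]
                out[max(0, dr) : H - max(0, -dr), max(0, dc) : W - max(0, -dc)] |= src
    return out


def flood_fill_components(mask):
    """8-connected components by explicit stack-based flood fill."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pix = []
            while stack:
                r, c = stack.pop()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            rows = [p[0] for p in pix]
            cols = [p[1] for p in pix]
            comps.append(
                (len(pix), min(rows), min(cols), max(rows) + 1, max(cols) + 1)
            )
    return comps


def largest_by_flood_fill(mask):
    comps = flood_fill_components(mask)
    return min(comps, key=lambda c: (-c[0], c[1], c[2]))


# ---------------------------------------------------------- variance filter

class TestVarianceFilter:
    def test_constant_image_is_zero(self):
        img = np.full((9, 9), 128.0)
        assert np.all(variance_filter(img, radius=1) == 0)

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_brute_force(self, rng, radius):
        gray = rng.uniform(0, 255, size=(11, 13))
        np.testing.assert_allclose(
            variance_filter(gray, radius), brute_force_variance(gray, radius), atol=1e-8
        )

    def test_center_spike(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        np.testing.assert_allclose(
            variance_filter(img, 1), brute_force_variance(img, 1), atol=1e-10
        )

    def test_step_edge_peaks_adjacent_to_edge(self):
        img = np.zeros((8, 10))
        img[:, 5:] = 255.0
        out = variance_filter(img, radius=1)
        interior = out[1:-1, 1:-1]
        peak_cols = {4, 5}  # columns straddling the 4|5 edge
        best = np.flatnonzero(interior.max(axis=0) == interior.max()) + 1
        assert set(best) == peak_cols

    def test_rejects_bad_radius(self):
        with pytest.raises(ValueError):
            variance_filter(np.zeros((5, 5)), radius=0)

    def test_rgb_collapsed_by_channel_mean(self, rng):
        rgb = rng.uniform(0, 255, size=(9, 9, 3))
        np.testing.assert_allclose(
            variance_filter(rgb, 1), variance_filter(rgb.mean(axis=2), 1)
        )


# ----------------------------------------------------------------- binarize

class TestBinarize:
    def test_bimodal_extremes(self, rng):
        img = rng.choice([0.0, 255.0], size=(16, 16))
        img[0, 0], img[0, 1] = 0.0, 255.0  # both values present
        np.testing.assert_array_equal(binarize(img), img == 255)

    def test_constant_warns_and_empty(self):
        with pytest.warns(UserWarning):
            mask = binarize(np.full((8, 8), 42.0))
        assert not mask.any()

    def test_threshold_matches_exhaustive_otsu_scan(self, rng):
        # two Gaussian intensity modes, quantized to integer levels
        img = np.concatenate(
            [rng.normal(60, 10, size=800), rng.normal(190, 12, size=800)]
        )
        img = np.clip(np.round(img), 0, 255).reshape(40, 40)
        mask = binarize(img)
        # exhaustive Otsu: maximize between-class variance over all thresholds
        best_t, best_v = None, -1.0
        for t in range(256):
            g0, g1 = img[img <= t], img[img > t]
            if g0.size == 0 or g1.size == 0:
                continue
            w0, w1 = g0.size / img.size, g1.size / img.size
            v = w0 * w1 * (g0.mean() - g1.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        np.testing.assert_array_equal(mask, img > best_t)


# ------------------------------------------------------------------- dilate

class TestDilate:
    def test_single_pixel_becomes_3x3_block(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        out = dilate(mask, 1)
        expected = np.zeros_like(mask)
        expected[2:5, 2:5] = True
        np.testing.assert_array_equal(out, expected)

    def test_zero_iterations_is_identity(self, rng):
        mask = rng.random((10, 10)) < 0.3
        np.testing.assert_array_equal(dilate(mask, 0), mask)

    def test_two_pixels_merge_after_two_iterations(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 2] = mask[4, 5] = True
        out = dilate(mask, 2)
        np.testing.assert_array_equal(out, brute_force_dilate(mask, 2))
        assert len(flood_fill_components(out)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((15, 15)) < 0.15
        prev = mask
        for k in (1, 2, 3):
            out = dilate(mask, k)
            np.testing.assert_array_equal(out, brute_force_dilate(mask, k))
            assert np.all(out | prev == out)  # superset of fewer iterations
            prev = out


# -------------------------------------------------------- largest component

class TestLargestComponent:
    def test_picks_larger_rectangle(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:6, 2:7] = True  # 20 px
        mask[10:18, 10:20] = True  # 80 px
        reg = largest_component(mask)
        assert (reg.row_min, reg.col_min, reg.row_max, reg.col_max) == (10, 10, 18, 20)
        assert reg.area == 80

    def test_empty_mask_raises(self):
        with pytest.raises(NoObjectError):
            largest_component(np.zeros((5, 5), dtype=bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        mask = rng.random((32, 32)) < 0.35
        if not mask.any():
            mask[0, 0] = True
        reg = largest_component(mask)
        area, r0, c0, r1, c1 = largest_by_flood_fill(mask)
        assert (reg.area, reg.row_min, reg.col_min, reg.row_max, reg.col_max) == (
            area, r0, c0, r1, c1,
        )


# -------------------------------------------------------------- square crop

class TestSquareCrop:
    def test_square_bbox_is_returned_as_is(self):
        img = np.arange(1000 * 1000).reshape(1000, 1000)
        reg = LarvaRegion(100, 200, 200, 300, 5000)
        out = square_crop(img, reg)
        np.testing.assert_array_equal(out, img[100:200, 200:300])

    def test_elongated_bbox_gets_centered_square(self):
        img = np.zeros((1000, 1000))
        reg = LarvaRegion(400, 475, 600, 525, 9000)  # 200x50 centered at (500,500)
        out = square_crop(img, reg)
        assert out.shape == (200, 200)
        # centered: rows 400:600, cols 400:600
        idx = np.arange(1000 * 1000).reshape(1000, 1000)
        np.testing.assert_array_equal(square_crop(idx, reg), idx[400:600, 400:600])

    def test_near_border_clips_to_rectangle_containing_bbox(self):
        img = np.zeros((1000, 1000))
        reg = LarvaRegion(400, 15, 600, 65, 9000)  # center 40 px from left edge
        out = square_crop(img, reg)
        assert out.shape[0] == 200 and out.shape[1] < 200
        idx = np.arange(1000 * 1000).reshape(1000, 1000)
        sub = square_crop(idx, reg)
        r0, c0 = np.unravel_index(sub[0, 0], idx.shape)
        r1, c1 = np.unravel_index(sub[-1, -1], idx.shape)
        assert r0 <= 400 and r1 + 1 >= 600 and c0 <= 15 and c1 + 1 >= 65

    def test_circular_region_tight_bounding_square(self):
        idx = np.arange(500 * 500).reshape(500, 500)
        reg = LarvaRegion(100, 100, 200, 196, 7000)  # ratio 100/96 < 1.2
        sub = square_crop(idx, reg, circular_ratio_max=1.2)
        assert sub.shape == (100, 100)
        r0, c0 = np.unravel_index(sub[0, 0], idx.shape)
        assert r0 == 100 and c0 in (97, 98)  # smaller dim expanded symmetrically


# ---------------------------------------------------------- locate_and_crop

class TestLocateAndCrop:
    def test_crop_contains_whole_ellipse(self):
        img, mask = make_ellipse_image()
        crop = locate_and_crop(img)
        dark = (crop.mean(axis=2) < 128).sum()
        assert dark >= mask.sum()  # every object pixel made it into the crop

    def test_blank_image_raises(self):
        img = np.full((128, 128, 3), 200, dtype=np.uint8)
        with pytest.raises(NoObjectError):
            locate_and_crop(img)

    def test_prefers_larva_over_debris(self):
        img, mask = make_ellipse_image(center=(100, 100), radii=(45, 20))
        img[200:207, 200:207] = 30  # small debris blob, ~50 px
        reg = locate_region(img)
        assert reg.row_min < 160 and reg.col_min < 160  # around the ellipse
        crop = locate_and_crop(img)
        assert (crop.mean(axis=2) < 128).sum() >= mask.sum()

    def test_idempotent_in_position(self):
        img, mask = make_ellipse_image()
        crop = locate_and_crop(img)
        crop2 = locate_and_crop(crop)
        assert (crop2.mean(axis=2) < 128).sum() >= mask.sum()

    def test_custom_params_still_capture(self):
        img, mask = make_ellipse_image()
        crop = locate_and_crop(img, CropParams(radius=3, dilations=3))
        assert (crop.mean(axis=2) < 128).sum() >= mask.sum()
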