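"""Puncta segmentation: thresholds, the inclusive area filter, mask levels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stedview.segmentation import (
    SegmentationParams,
    auto_threshold,
    detect_puncta,
    measure_within_mask,
)
from stedview.synthetic import grid_scene_spec, render_scene


def otsu_exhaustive(image):
    """Independent Otsu: search all integer thresholds for the one that
    maximizes between-class variance."""
    vals = image.ravel()
    best_t, best_v = None, -1.0
    for t in range(int(vals.min()), int(vals.max())):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def blocks_image(areas_px, pixel_size=100.0, value=100.0):
    """One rectangular component per requested pixel area, well separated."""
    img = np.zeros((200, 200))
    x = 5
    for a in areas_px:
        w = int(np.ceil(np.sqrt(a)))
        h = int(np.ceil(a / w))
        block = np.zeros((h, w))
        block.flat[:a] = value
        img[5 : 5 + h, x : x + w] = block
        x += w + 5
    return img


class TestAutoThreshold:
    def test_all_zero_image_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = auto_threshold(np.zeros((10, 10)))
        assert not mask.any()

    def test_bimodal_image_matches_exhaustive_otsu(self):
        rng = np.random.default_rng(0)
        img = np.full((60, 60), 10.0)
        img[20:40, 20:40] = 100.0
        img += rng.normal(0, 1, img.shape)
        t = otsu_exhaustive(img.astype(int))
        mask = auto_threshold(img)
        oracle = img.astype(int) > t
        assert (mask == oracle).mean() > 0.999

    def test_fixed_threshold(self):
        img = np.arange(9.0).reshape(3, 3)
        assert auto_threshold(img, "fixed:4").sum() == 4

    def test_high_snr_scene_mask_covers_true_footprints(self):
        spec = grid_scene_spec([0.0] * 4, seed=3, noise="none")
        scene = render_scene(spec)
        mask = auto_threshold(scene.channel("vesicle"))
        px = spec.pixel_size
        xs = np.arange(scene.images["scaffold"].shape[1]) * px
        ys = np.arange(scene.images["scaffold"].shape[0]) * px
        X, Y = np.meshgrid(xs, ys)
        covered = []
        for _, row in scene.truth.iterrows():
            nx = -row.orientation_y * row.cloud_side
            ny = row.orientation_x * row.cloud_side
            ccx = row.center_x_nm + nx * row.cloud_radius_nm
            ccy = row.center_y_nm + ny * row.cloud_radius_nm
            inside = (X - ccx) ** 2 + (Y - ccy) ** 2 <= (0.8 * row.cloud_radius_nm) ** 2
            covered.append(mask[inside].mean())
        assert min(covered) >= 0.9


class TestDetectPuncta:
    def test_size_filter_example(self):
        # pixel 100 nm -> 1 px = 0.01 um^2; areas 0.2, 0.5, 2.5 um^2
        img = blocks_image([20, 50, 250], pixel_size=100.0)
        table = detect_puncta(img, pixel_size=100.0)
        assert table.count == 1
        assert table.puncta.area_um2.iloc[0] == pytest.approx(0.5)

    def test_lower_bound_inclusive(self):
        img = blocks_image([40], pixel_size=100.0)  # exactly 0.4 um^2
        assert detect_puncta(img, pixel_size=100.0).count == 1

    def test_empty_mask_gives_zero_count_missing_means(self):
        with pytest.warns(UserWarning, match="constant"):
            table = detect_puncta(np.zeros((50, 50)), pixel_size=100.0)
        assert table.count == 0 and table.density_per_100um2 == 0.0
        assert np.isnan(table.mean_area_um2) and np.isnan(table.mean_intensity)

    def test_pixel_size_required(self):
        with pytest.raises(ValueError, match="pixel_size"):
            detect_puncta(np.ones((5, 5)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=300), min_size=1, max_size=8))
    def test_area_filter_matches_brute_force(self, areas):
        """Retained component set equals brute-force pixel-count enumeration."""
        px = 100.0
        img = blocks_image(areas, pixel_size=px)
        params = SegmentationParams()
        table = detect_puncta(img, params, pixel_size=px)
        expected = sorted(
            a * (px / 1000.0) ** 2
            for a in areas
            if params.min_area <= a * (px / 1000.0) ** 2 <= params.max_area
        )
        got = sorted(table.puncta.area_um2)
        assert np.allclose(got, expected)

    def test_density_invariant_under_tiling(self):
        img = blocks_image([50, 60], pixel_size=100.0)
        tiled = np.block([[img, img], [img, img]])
        t1 = detect_puncta(img, pixel_size=100.0)
        t4 = detect_puncta(tiled, pixel_size=100.0)
        assert t4.count == 4 * t1.count
        assert t4.density_per_100um2 == pytest.approx(t1.density_per_100um2)

    def test_recovers_true_count_on_clean_scene(self):
        spec = grid_scene_spec([0.0] * 9, seed=5, noise="none")
        scene = render_scene(spec)
        table = detect_puncta(scene.channel("vesicle"), pixel_size=spec.pixel_size)
        assert table.count == 9


class TestMeasureWithinMask:
    def test_full_mask_equals_global_mean(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 50, (20, 20))
        assert measure_within_mask(img, np.ones_like(img, bool)) == pytest.approx(img.mean())

    def test_constant_image(self):
        img = np.full((10, 10), 7.0)
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        assert measure_within_mask(img, mask) == 7.0

    def test_bright_region_only(self):
        img = np.full((10, 10), 10.0)
        img[:5] = 100.0
        assert measure_within_mask(img, img == 100.0) == 100.0

    def test_empty_mask_is_missing(self):
        with pytest.warns(UserWarning, match="empty mask"):
            v = measure_within_mask(np.ones((5, 5)), np.zeros((5, 5), bool))
        assert np.isnan(v)
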