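"""Unit and property tests for the shared image/measurement primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmjquant import (
    Calibration,
    ChannelImage,
    DegenerateHistogramError,
    EmptyMaskError,
    EmptyRegionError,
    RegionMask,
    SeedNotInForegroundError,
    chain_code_perimeter,
    clear_region,
    convert_to_8bit,
    enlarge_region,
    otsu_threshold,
    region_stats,
    select_component,
)
from _oracles import enlarge_brute_force, otsu_brute_force, region_stats_naive
from conftest import img8, mask_of


# ---------------------------------------------------------------------------
# Otsu thresholding


class TestOtsu:
    def test_two_value_image_separates_classes(self):
        px = np.array([[0] * 50 + [200] * 50], dtype=np.uint8)
        img = img8(px)
        threshold, mask = otsu_threshold(img)
        assert (mask.mask == (px == 200)).all()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(img8(np.full((5, 5), 7)))

    def test_two_values_in_one_bin_raises_on_12bit(self):
        # values 3 and 7 share the first of 256 sixteen-wide bins
        px = np.array([[3, 7, 3, 7]], dtype=np.uint16)
        img = ChannelImage(px, Calibration(0.1, 12))
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(img)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_within_class_minimizer(self, seed):
        """Bimodal 8-bit mixtures: threshold equals the brute-force minimizer
        of the within-class variance over all 256 candidates."""
        rng = np.random.default_rng(seed)
        px = (
            np.clip(
                np.concatenate(
                    [rng.normal(50, 10, 2000), rng.normal(180, 10, 2000)]
                ),
                0,
                255,
            )
            .astype(np.uint8)
            .reshape(40, 100)
        )
        img = img8(px)
        threshold, mask = otsu_threshold(img)
        assert threshold == otsu_brute_force(px, 8)
        assert (mask.mask == (px > threshold)).all()

    def test_matches_skimage_on_8bit(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        px = (
            np.clip(
                np.concatenate(
                    [rng.normal(60, 15, 3000), rng.normal(190, 12, 2000)]
                ),
                0,
                255,
            )
            .astype(np.uint8)
            .reshape(50, 100)
        )
        assert otsu_threshold(img8(px))[0] == threshold_otsu(px, nbins=256)

    def test_12bit_threshold_is_bin_aligned(self):
        rng = np.random.default_rng(3)
        px = (
            np.clip(
                np.concatenate(
                    [rng.normal(800, 100, 2000), rng.normal(3000, 150, 2000)]
                ),
                0,
                4095,
            )
            .astype(np.uint16)
            .reshape(40, 100)
        )
        img = ChannelImage(px, Calibration(0.1, 12))
        threshold, _ = otsu_threshold(img)
        assert threshold == otsu_brute_force(px, 12)
        assert (threshold + 1) % 16 == 0  # top of a 16-wide bin


# ---------------------------------------------------------------------------
# component selection


class TestSelectComponent:
    def _two_components(self):
        m = np.zeros((20, 20), dtype=bool)
        m[1:3, 1:6] = True  # 10 px
        m[8:13, 8:16] = True  # 40 px
        return mask_of(m)

    def test_largest_picks_bigger_component(self):
        sel = select_component(self._two_components(), "largest")
        assert sel.area_px == 40
        assert sel.mask[10, 10]

    def test_seed_picks_containing_component(self):
        sel = select_component(self._two_components(), (1, 1))
        assert sel.area_px == 10

    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1] = m[2, 2] = True
        sel = select_component(mask_of(m), (1, 1))
        assert sel.area_px == 2

    def test_seed_on_background_raises(self):
        with pytest.raises(SeedNotInForegroundError):
            select_component(self._two_components(), (0, 0))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            select_component(RegionMask.empty((5, 5)), "largest")

    def test_size_tie_breaks_to_first_row_major_member(self):
        m = np.zeros((10, 10), dtype=bool)
        m[6:8, 0:2] = True  # 4 px, starts at row 6
        m[0:2, 6:8] = True  # 4 px, starts at row 0 -> wins
        sel = select_component(mask_of(m), "largest")
        assert sel.mask[0, 6] and not sel.mask[6, 0]

    def test_output_is_subset_and_connected(self):
        from scipy import ndimage

        rng = np.random.default_rng(5)
        m = rng.random((30, 30)) < 0.3
        m[0, 0] = True
        sel = select_component(mask_of(m), "largest")
        assert (sel.mask <= m).all()
        _, n = ndimage.label(sel.mask, structure=np.ones((3, 3)))
        assert n == 1


# ---------------------------------------------------------------------------
# calibrated enlargement


class TestEnlargeRegion:
    def test_distance_zero_is_identity(self, cal8):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        roi = mask_of(m)
        assert (enlarge_region(roi, 0.0, cal8).mask == m).all()

    def test_unit_distance_adds_edge_neighbours_only(self, cal8):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        out = enlarge_region(mask_of(m), 1.0, cal8).mask
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = expected[1, 2] = expected[3, 2] = True
        expected[2, 1] = expected[2, 3] = True  # diagonals at sqrt(2) excluded
        assert (out == expected).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(5, 33)), int(rng.integers(5, 33)))
        m = rng.random(shape) < 0.1
        m[0, 0] = True
        d_um = float(rng.uniform(0, 1.5))
        cal = Calibration(0.1, 8)
        got = enlarge_region(mask_of(m), d_um, cal).mask
        assert (got == enlarge_brute_force(m, d_um / 0.1)).all()

    def test_monotone_in_distance_and_superset_of_roi(self, cal8):
        rng = np.random.default_rng(11)
        m = rng.random((25, 25)) < 0.05
        m[12, 12] = True
        roi = mask_of(m)
        prev = roi.mask
        for d in (0.0, 0.7, 1.3, 2.9):
            cur = enlarge_region(roi, d, cal8).mask
            assert (prev <= cur).all()
            assert (roi.mask <= cur).all()
            prev = cur


# ---------------------------------------------------------------------------
# clearing and conservation


class TestClearRegion:
    def test_empty_roi_leaves_image_unchanged(self):
        img = img8(np.arange(16).reshape(4, 4))
        out = clear_region(img, RegionMask.empty((4, 4)))
        assert (out.pixels == img.pixels).all()

    def test_full_roi_zeroes_image(self):
        img = img8(np.arange(16).reshape(4, 4))
        out = clear_region(img, RegionMask.full((4, 4)))
        assert out.pixels.sum() == 0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_intensity_conservation(self, seed):
        rng = np.random.default_rng(seed)
        img = img8(rng.integers(0, 256, size=(12, 12)))
        roi = mask_of(rng.random((12, 12)) < 0.4)
        cleared = clear_region(img, roi)
        total = int(img.pixels.sum())
        inside = int(img.pixels[roi.mask].sum())
        assert int(cleared.pixels.sum()) == total - inside


# ---------------------------------------------------------------------------
# region statistics


class TestRegionStats:
    def test_three_value_region(self, cal8):
        img = img8([[1, 2, 3]])
        s = region_stats(img, RegionMask.full((1, 3)))
        assert s.area_um2 == 3.0
        assert s.mean == 2.0
        assert s.median == 2
        assert s.raw_integrated_density == 6
        assert s.skewness == 0.0

    def test_mode_tie_breaks_to_smaller_value(self):
        img = img8([[0, 0, 255, 255]])
        s = region_stats(img, RegionMask.full((1, 4)))
        assert s.mean == 127.5
        assert s.mode == 0
        assert s.min == 0 and s.max == 255
        assert s.median == 0  # lower middle of an even-count region

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            region_stats(img8([[1]]), RegionMask.empty((1, 1)))

    def test_constant_region_has_zero_moments(self):
        s = region_stats(img8(np.full((3, 3), 9)), RegionMask.full((3, 3)))
        assert s.std_dev == 0.0 and s.skewness == 0.0 and s.kurtosis == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_every_field_matches_naive_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        img = img8(rng.integers(0, 256, size=(20, 20)), pixel_size_um=0.1)
        m = np.zeros((20, 20), dtype=bool)
        idx = rng.choice(400, size=100, replace=False)
        m.ravel()[idx] = True
        s = region_stats(img, mask_of(m))
        want = region_stats_naive(img.pixels[m])
        assert s.n_pixels == want["n"]
        assert s.area_um2 == pytest.approx(100 * 0.01)
        assert s.mean == pytest.approx(want["mean"])
        assert s.std_dev == pytest.approx(want["std_dev"])
        assert s.min == want["min"] and s.max == want["max"]
        assert s.raw_integrated_density == want["raw_integrated_density"]
        assert s.median == want["median"]
        assert s.mode == want["mode"]
        assert s.skewness == pytest.approx(want["skewness"])
        assert s.kurtosis == pytest.approx(want["kurtosis"])
        assert s.integrated_density == pytest.approx(s.area_um2 * s.mean)

    def test_raw_integrated_density_additive_over_disjoint_regions(self):
        rng = np.random.default_rng(2)
        img = img8(rng.integers(0, 256, size=(10, 10)))
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:5] = True
        b[5:] = True
        sa = region_stats(img, mask_of(a)).raw_integrated_density
        sb = region_stats(img, mask_of(b)).raw_integrated_density
        sfull = region_stats(img, RegionMask.full((10, 10))).raw_integrated_density
        assert sa + sb == sfull


# ---------------------------------------------------------------------------
# 8-bit conversion


class TestConvertTo8bit:
    def test_endpoints_and_midpoint(self):
        px = np.array([[0, 2048, 4095]], dtype=np.uint16)
        img = ChannelImage(px, Calibration(0.1, 12))
        out = convert_to_8bit(img)
        assert list(out.pixels[0]) == [0, 128, 255]
        assert out.calibration.bit_depth == 8

    def test_8bit_input_unchanged(self):
        img = img8([[5, 250]])
        assert convert_to_8bit(img) is img

    def test_monotone_on_exhaustive_12bit_sweep(self):
        px = np.arange(4096, dtype=np.uint16).reshape(64, 64)
        out = convert_to_8bit(ChannelImage(px, Calibration(0.1, 12))).pixels
        flat = out.ravel()
        assert (np.diff(flat.astype(int)) >= 0).all()
        assert flat[0] == 0 and flat[-1] == 255


# ---------------------------------------------------------------------------
# chain-code perimeter


class TestChainCodePerimeter:
    @pytest.mark.parametrize(
        "mask, expected",
        [
            ([[1]], 4.0),  # single pixel: pixel outline
            ([[1, 1]], 2.0),  # domino: out-and-back centre trace
            (np.ones((3, 3)), 8.0),  # ring of 8 boundary centres
            (np.ones((1, 5)), 8.0),  # line: 2*(n-1)
        ],
    )
    def test_known_shapes(self, mask, expected, cal8):
        assert chain_code_perimeter(mask_of(mask), cal8) == pytest.approx(expected)

    def test_diagonal_steps_count_sqrt2(self, cal8):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 0] = m[1, 1] = m[2, 2] = True  # diagonal line of 3
        assert chain_code_perimeter(mask_of(m), cal8) == pytest.approx(4 * np.sqrt(2))

    def test_disk_rounder_than_line(self, cal8):
        r = 10
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = yy ** 2 + xx ** 2 <= r * r
        p_disk = chain_code_perimeter(mask_of(disk), cal8)
        a_disk = disk.sum()
        line = np.ones((1, 40), dtype=bool)
        p_line = chain_code_perimeter(mask_of(line), cal8)
        circ_disk = 4 * np.pi * a_disk / p_disk ** 2
        circ_line = 4 * np.pi * 40 / p_line ** 2
        assert circ_disk > 0.85 > 0.3 > circ_line

    def test_multi_component_mask_sums_components(self, cal8):
        m = np.zeros((8, 8), dtype=bool)
        m[0, 0] = True  # 4.0
        m[4:7, 4:7] = True  # 8.0
        assert chain_code_perimeter(mask_of(m), cal8) == pytest.approx(12.0)

    def test_scales_with_pixel_size(self):
        m = np.ones((3, 3), dtype=bool)
        assert chain_code_perimeter(
            mask_of(m), Calibration(0.1, 8)
        ) == pytest.approx(0.8)
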