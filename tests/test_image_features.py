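"""Unit and property tests of the low-level visual feature extractor."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import circle_perimeter

from viewfeat.config import ExtractionConfig
from viewfeat.image_features import (
    FEATURE_FIELDS,
    FeatureVector,
    ImageFormatError,
    aggregate_participant,
    box_count,
    channel_stats,
    color_ratio,
    default_box_sizes,
    edge_densities,
    edge_map,
    entropy,
    extract_features,
    fractal_dimension_binary,
    hue_stats,
    sky_ratio,
    to_hsv,
)

from conftest import solid


# ---------------------------------------------------------------------------
# colour conversion and statistics


class TestToHsv:
    def test_red_maps_to_hue_zero(self):
        assert np.all(to_hsv(solid((255, 0, 0))).hue == 0.0)

    def test_cyan_maps_to_pi_seam(self):
        hue = to_hsv(solid((0, 255, 255))).hue
        assert np.allclose(np.abs(hue), np.pi)

    def test_grey_is_achromatic(self):
        hsv = to_hsv(solid((128, 128, 128)))
        assert np.all(hsv.sat == 0.0)
        assert np.allclose(hsv.val, 128 / 255)

    def test_hue_range_is_half_open(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        hsv = to_hsv(img)
        assert hsv.hue.min() > -np.pi and hsv.hue.max() <= np.pi

    def test_rejects_non_rgb(self):
        with pytest.raises(ImageFormatError):
            to_hsv(np.zeros((8, 8), np.uint8))


class TestHueStats:
    def test_uniform_red_zero_dispersion(self):
        mean, sd, flags = hue_stats(to_hsv(solid((255, 0, 0))))
        assert mean == 0.0 and sd == pytest.approx(0.0, abs=1e-12)
        assert not flags

    def test_half_red_half_green_matches_vector_sum_oracle(self):
        img = solid((255, 0, 0), (16, 16))
        img[8:] = (0, 255, 0)
        # independent per-pixel oracle through colorsys
        angles = []
        for row in img.reshape(-1, 3):
            h, s, v = colorsys.rgb_to_hsv(*(row / 255.0))
            theta = h * 2 * np.pi
            angles.append(theta - 2 * np.pi if theta > np.pi else theta)
        angles = np.array(angles)
        r = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
        expect_mean = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
        expect_sd = np.sqrt(2 * (1 - r))
        mean, sd, _ = hue_stats(to_hsv(img))
        assert mean == pytest.approx(expect_mean, abs=1e-12)
        assert mean == pytest.approx(np.pi / 3, abs=1e-12)
        assert sd == pytest.approx(expect_sd, abs=1e-12)

    def test_antipodal_mixture_flagged_unstable(self):
        img = solid((255, 0, 0), (16, 16))
        img[8:] = (0, 255, 255)
        mean, sd, flags = hue_stats(to_hsv(img))
        assert flags.get("hue_mean_unstable")
        assert np.isnan(mean)
        assert sd == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_achromatic_image_flagged_not_silent_zero(self):
        mean, sd, flags = hue_stats(to_hsv(solid((99, 99, 99))))
        assert flags.get("hue_undefined")
        assert np.isnan(mean) and np.isnan(sd)


class TestChannelStats:
    @pytest.mark.parametrize(
        "img, expect",
        [
            (solid((0, 0, 0)), (0.0, 0.0, 0.0, 0.0)),
            (solid((255, 255, 255)), (0.0, 0.0, 1.0, 0.0)),
        ],
    )
    def test_constant_images(self, img, expect):
        s_m, s_sd, v_m, v_sd = channel_stats(to_hsv(img))
        assert (s_m, s_sd, v_m, v_sd) == pytest.approx(expect)

    def test_half_black_half_white_two_point_moments(self):
        img = solid((0, 0, 0), (16, 16))
        img[8:] = 255
        _, _, v_m, v_sd = channel_stats(to_hsv(img))
        assert v_m == pytest.approx(0.5) and v_sd == pytest.approx(0.5)


class TestColorAndSkyRatios:
    def test_uniform_green_is_all_green(self):
        cfg = ExtractionConfig()
        assert color_ratio(solid((0, 200, 0)), cfg.green_band, cfg) == 1.0

    def test_red_has_no_green(self):
        cfg = ExtractionConfig()
        assert color_ratio(solid((255, 0, 0)), cfg.green_band, cfg) == 0.0

    def test_quarter_green_rectangle_counted_exactly(self):
        cfg = ExtractionConfig()
        img = solid((255, 0, 0), (32, 32))
        img[:16, :16] = (0, 200, 0)  # exactly 25% of the area
        assert color_ratio(img, cfg.green_band, cfg) == pytest.approx(0.25)

    def test_empty_band_rejected_by_config(self):
        with pytest.raises(ValueError):
            ExtractionConfig(green_band=(90.0, 90.0))

    def test_fully_blackened_mask_gives_zero(self):
        assert sky_ratio(solid((0, 0, 0))) == 0.0

    @pytest.mark.parametrize("sky_rgb", [(80, 120, 230), (235, 235, 235)])
    def test_top_band_fraction_recovered(self, sky_rgb):
        # 30% blue sky and 30% overcast white sky, rest mask black
        img = solid((0, 0, 0), (40, 20))
        img[:12] = sky_rgb
        assert sky_ratio(img) == pytest.approx(0.30)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ratios_bounded(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        cfg = ExtractionConfig()
        for band in (cfg.green_band, cfg.blue_band):
            assert 0.0 <= color_ratio(img, band, cfg) <= 1.0
        assert 0.0 <= sky_ratio(img, cfg) <= 1.0


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(solid((37, 37, 37))) == 0.0

    def test_two_equal_levels_one_bit(self):
        img = solid((0, 0, 0), (16, 16))
        img[8:] = 200
        assert entropy(img) == pytest.approx(1.0)

    def test_uniform_histogram_saturates_at_eight_bits(self):
        levels = np.repeat(np.arange(256, dtype=np.uint8), 4).reshape(32, 32)
        img = np.stack([levels] * 3, axis=-1)
        assert entropy(img) == pytest.approx(8.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        vals = {entropy(np.rot90(img, k).copy()) for k in range(4)}
        assert len(vals) == 1


# ---------------------------------------------------------------------------
# edges


class TestEdges:
    def test_constant_image_has_no_edges(self):
        assert not edge_map(solid((120, 120, 120), (32, 32))).any()

    def test_sharp_step_yields_single_column_at_gradient_maximum(self):
        img = solid((0, 0, 0), (32, 64))
        img[:, 31] = 100  # ramp midpoint so the gradient peak is unique
        img[:, 32:] = 200
        edges = edge_map(img)
        cols = np.unique(np.nonzero(edges)[1])
        assert len(cols) == 1
        # oracle: column of maximum horizontal luma gradient
        from scipy.ndimage import gaussian_filter

        g = gaussian_filter(img[..., 0].astype(float), 1.4)
        grad_col = np.abs(np.diff(g, axis=1)).mean(axis=0).argmax()
        assert abs(int(cols[0]) - int(grad_col)) <= 1

    def test_low_amplitude_noise_below_threshold_gives_empty_map(self):
        rng = np.random.default_rng(3)
        img = (128 + rng.integers(-2, 3, (32, 32))).astype(np.uint8)
        assert not edge_map(np.stack([img] * 3, -1)).any()

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            edge_map(solid((0, 0, 0), (2, 32)))

    def test_empty_edge_raster_gives_zero_densities(self):
        assert edge_densities(np.zeros((64, 64), bool)) == (0.0, 0.0, 0.0)

    def test_full_width_line_is_entirely_straight(self):
        edges = np.zeros((512, 512), bool)
        edges[200, :] = True
        ed, sed, nsed = edge_densities(edges)
        assert ed == pytest.approx(512 / 512**2)
        assert sed == pytest.approx(ed)
        assert nsed == 0.0

    def test_circle_outline_is_nonstraight(self):
        edges = np.zeros((512, 512), bool)
        rr, cc = circle_perimeter(256, 256, 100)
        edges[rr, cc] = True
        ed, sed, nsed = edge_densities(edges)
        assert sed == 0.0
        assert nsed == pytest.approx(ed)

    def test_partition_identity_on_arbitrary_rasters(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            edges = rng.random((64, 64)) < 0.08
            edges[rng.integers(64), :] = True  # guarantee one line
            ed, sed, nsed = edge_densities(edges)
            assert sed + nsed == pytest.approx(ed, abs=1e-15)
            assert 0.0 <= sed <= ed <= 1.0

    def test_translation_invariance_of_edge_density(self):
        img = solid((30, 30, 30), (64, 64))
        img[20:40, 20:40] = 220
        base = edge_map(img).sum()
        shifted = np.roll(img, (5, 5), axis=(0, 1))
        assert abs(int(edge_map(shifted).sum()) - int(base)) <= 8


# ---------------------------------------------------------------------------
# box counting / fractal dimension


def brute_force_box_count(binary, size, offset=(0, 0)):
    """Independent triple-loop box counter."""
    h, w = binary.shape
    oy, ox = offset
    count = 0
    r0 = -(oy % size)
    c0 = -(ox % size)
    for top in range(r0, h, size):
        for left in range(c0, w, size):
            box = binary[max(top, 0) : top + size, max(left, 0) : left + size]
            if box.size and box.any():
                count += 1
    return count


class TestBoxCounting:
    @pytest.mark.parametrize("shape", [(16, 16), (33, 17), (48, 64), (64, 64)])
    def test_counts_equal_brute_force_battery(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        for density in (0.02, 0.2, 0.7):
            binary = rng.random(shape) < density
            for size in range(2, 9):
                for off in ((0, 0), (1, 2)):
                    assert box_count(binary, size, off) == brute_force_box_count(
                        binary, size, off
                    ), (shape, density, size, off)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_adding_foreground_never_decreases_counts(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((32, 32)) < 0.1
        grown = binary | (rng.random((32, 32)) < 0.1)
        for size in (2, 3, 5, 8):
            assert box_count(grown, size) >= box_count(binary, size)

    def test_filled_plane_dimension_two(self):
        fd, flags = fractal_dimension_binary(np.ones((512, 512), bool))
        assert fd == pytest.approx(2.0, abs=0.05)
        assert "fd_out_of_range" not in flags

    def test_straight_line_dimension_one(self):
        binary = np.zeros((512, 512), bool)
        binary[256, :] = True
        fd, _ = fractal_dimension_binary(binary)
        assert fd == pytest.approx(1.0, abs=0.1)

    def test_sierpinski_triangle_self_similarity_dimension(self):
        i, j = np.meshgrid(np.arange(512), np.arange(512), indexing="ij")
        sier = (i & j) == 0  # depth-7+ Sierpinski pattern on a 512 grid
        sizes = default_box_sizes(sier.shape)
        # optimized counts must equal the brute-force oracle here too
        for s in sizes:
            assert box_count(sier, s) == brute_force_box_count(sier, s)
        fd, _ = fractal_dimension_binary(sier)
        assert fd == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_empty_foreground_flagged(self):
        fd, flags = fractal_dimension_binary(np.zeros((64, 64), bool))
        assert np.isnan(fd) and flags.get("fd_undefined")

    def test_too_few_box_sizes_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension_binary(np.ones((12, 12), bool))


# ---------------------------------------------------------------------------
# full extraction + aggregation


class TestExtractAndAggregate:
    def test_all_green_scene(self):
        fv = extract_features(solid((40, 180, 40), (32, 32)), solid((0, 0, 0), (32, 32)))
        assert fv.green_ratio == 1.0 and fv.sky_ratio == 0.0

    def test_missing_mask_flags_sky_ratio(self):
        fv = extract_features(solid((40, 180, 40), (32, 32)), None)
        assert np.isnan(fv.sky_ratio) and fv.flags.get("sky_mask_missing")

    def test_mask_dimension_mismatch_rejected(self):
        with pytest.raises(ImageFormatError):
            extract_features(
                solid((40, 180, 40), (32, 32)), solid((0, 0, 0), (16, 16))
            )

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        mask = img.copy()
        mask[24:] = 0
        a = extract_features(img, mask).as_array()
        b = extract_features(img, mask).as_array()
        assert np.array_equal(a, b, equal_nan=True)

    def test_ranges_respected_on_random_images(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
            fv = extract_features(img, img)
            for name in (
                "sat_mean", "bright_mean", "green_ratio", "blue_ratio",
                "sky_ratio", "edge_density", "straight_edge_density",
                "nonstraight_edge_density",
            ):
                assert 0.0 <= getattr(fv, name) <= 1.0
            assert 0.0 <= fv.entropy <= 8.0
            assert fv.straight_edge_density + fv.nonstraight_edge_density == (
                pytest.approx(fv.edge_density, abs=1e-15)
            )

    def test_single_window_aggregation_is_identity(self):
        fv = extract_features(solid((40, 180, 40), (32, 32)))
        agg = aggregate_participant([fv])
        for name in FEATURE_FIELDS:
            a, b = getattr(agg, name), getattr(fv, name)
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_entropy_averages_arithmetically(self):
        def fv_with(entropy_val):
            kw = {name: 0.5 for name in FEATURE_FIELDS}
            kw["entropy"] = entropy_val
            return FeatureVector(**kw)

        agg = aggregate_participant([fv_with(7.55), fv_with(7.26)])
        assert agg.entropy == pytest.approx(7.405)

    def test_hue_mean_averages_circularly_across_the_seam(self):
        def fv_with(hue):
            kw = {name: 0.1 for name in FEATURE_FIELDS}
            kw["hue_mean"] = hue
            return FeatureVector(**kw)

        agg = aggregate_participant([fv_with(3.0), fv_with(-3.0)])
        # vector-sum oracle: mean of unit vectors at +-3 rad points to +-pi
        expect = np.arctan2(
            (np.sin(3.0) + np.sin(-3.0)) / 2, (np.cos(3.0) + np.cos(-3.0)) / 2
        )
        assert abs(agg.hue_mean) == pytest.approx(np.pi, abs=1e-9)
        assert agg.hue_mean == pytest.approx(expect, abs=1e-9) or abs(
            agg.hue_mean
        ) == pytest.approx(abs(expect), abs=1e-9)

    def test_empty_aggregate_rejected(self):
        with pytest.raises(ValueError):
            aggregate_participant([])
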