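"""Histogram feature extraction: segmentation, barycenter, FWHM, GD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytostress import (
    ChannelHistogram,
    UndefinedFeatureError,
    barycenter,
    channel_histogram,
    fwhm,
    green_dominance,
    image_feature_row,
    integral_area,
    segment_plant,
)


def hist(spec: dict, channel: str = "G") -> ChannelHistogram:
    counts = np.zeros(256, dtype=int)
    for value, count in spec.items():
        counts[value] = count
    return ChannelHistogram(counts=counts, channel=channel)


class TestSegmentation:
    def test_uniform_image_gives_empty_mask(self):
        image = np.full((20, 30, 3), 7, dtype=np.uint8)
        assert not segment_plant(image, bg_level=7).any()

    def test_tol_zero_selects_every_differing_pixel(self):
        image = np.zeros((20, 30, 3), dtype=np.uint8)
        image[3, 4, 1] = 1  # a single barely-different pixel
        mask = segment_plant(image, bg_level=0, tol=0, min_size=1)
        assert mask.sum() == 1 and mask[3, 4]

    def test_small_components_removed(self):
        image = np.zeros((40, 40, 3), dtype=np.uint8)
        image[1:3, 1:3] = 200          # 4 px speck: removed
        image[10:20, 10:20] = 200      # 100 px blob: kept
        mask = segment_plant(image)
        assert mask.sum() == 100 and mask[15, 15] and not mask[1, 1]


class TestChannelHistogram:
    def test_empty_mask_gives_zero_histogram(self):
        image = np.random.default_rng(0).integers(0, 255, (10, 10, 3), dtype=np.uint8)
        h = channel_histogram(image, np.zeros((10, 10), bool), "R")
        assert h.counts.sum() == 0

    def test_counts_match_pixel_values(self):
        image = np.zeros((1, 3, 3), dtype=np.uint8)
        image[0, :, 1] = [10, 10, 20]
        h = channel_histogram(image, np.ones((1, 3), bool), "G")
        assert h.counts[10] == 2 and h.counts[20] == 1 and h.counts.sum() == 3

    def test_total_equals_mask_pixel_count(self):
        rng = np.random.default_rng(1)
        image = rng.integers(0, 256, (30, 30, 3), dtype=np.uint8)
        mask = rng.random((30, 30)) < 0.4
        h = channel_histogram(image, mask, "B")
        assert h.counts.sum() == mask.sum()


class TestIntegralArea:
    @pytest.mark.parametrize(
        "spec, expected",
        [({}, 0), ({10: 2, 20: 1}, 3), ({0: 5, 50: 7}, 7)],
    )
    def test_zero_bin_excluded(self, spec, expected):
        assert integral_area(hist(spec)) == expected


class TestBarycenter:
    def test_point_mass(self):
        assert barycenter(hist({100: 12345})) == 100.0

    def test_hand_weighted_mean(self):
        assert barycenter(hist({50: 1, 150: 3})) == 125.0

    def test_zero_bin_does_not_contribute(self):
        assert barycenter(hist({0: 1000, 100: 1})) == 100.0

    def test_empty_histogram_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            barycenter(hist({}))


class TestFWHM:
    def test_single_spike_width_one(self):
        result = fwhm(hist({100: 50}), smooth_window=1)
        assert result.width == pytest.approx(1.0)
        assert not result.one_sided

    def test_boundary_spike_is_one_sided(self):
        result = fwhm(hist({255: 50}), smooth_window=1)
        assert result.width == pytest.approx(1.0)
        assert result.one_sided

    def test_triangular_histogram_hand_geometry(self):
        spec = {v: 10 - abs(v - 100) for v in range(91, 110)}
        result = fwhm(hist(spec), smooth_window=1)
        assert result.width == pytest.approx(10.0)  # crossings at 95 and 105

    def test_discretized_gaussian_matches_closed_form(self):
        v = np.arange(256)
        sd = 10.0
        counts = np.rint(1e6 * np.exp(-((v - 128.0) ** 2) / (2 * sd**2))).astype(int)
        h = ChannelHistogram(counts=counts, channel="G")
        expected = 2.3548 * sd
        assert fwhm(h).width == pytest.approx(expected, rel=0.03)

    def test_empty_histogram_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            fwhm(hist({}))


class TestGreenDominance:
    @pytest.mark.parametrize(
        "rgb, percent",
        [
            ((122.18904, 155.77954, 94.29842), 41.8),  # well-watered reference
            ((161.17829, 183.06305, 119.85221), 39.4),  # after 6 days of drought
        ],
    )
    def test_reference_barycenters(self, rgb, percent):
        assert green_dominance(*rgb).percent == percent

    def test_equal_channels_give_one_third(self):
        assert green_dominance(80.0, 80.0, 80.0).gd == pytest.approx(1 / 3)

    def test_nonpositive_barycenter_rejected(self):
        with pytest.raises(UndefinedFeatureError):
            green_dominance(0.0, 100.0, 100.0)

    @given(
        r=st.floats(1.0, 255.0),
        g=st.floats(1.0, 255.0),
        b=st.floats(1.0, 255.0),
        delta=st.floats(0.1, 50.0),
    )
    def test_bounded_and_monotone_in_green(self, r, g, b, delta):
        gd = green_dominance(r, g, b).gd
        assert 0.0 < gd < 1.0
        assert green_dominance(r, g + delta, b).gd > gd


class TestHistogramInvariances:
    @given(scale=st.integers(2, 50))
    def test_count_scale_invariance(self, scale):
        spec = {40: 3, 50: 10, 60: 7, 80: 2}
        h1 = hist(spec)
        h2 = hist({v: c * scale for v, c in spec.items()})
        assert barycenter(h1) == pytest.approx(barycenter(h2))
        assert fwhm(h1, 1).width == pytest.approx(fwhm(h2, 1).width)

    @given(delta=st.integers(-30, 100))
    def test_shift_covariance(self, delta):
        spec = {40: 3, 50: 10, 60: 7}
        shifted = hist({v + delta: c for v, c in spec.items()})
        assert barycenter(shifted) == pytest.approx(barycenter(hist(spec)) + delta)


class TestFeatureRow:
    def test_empty_mask_flags_all_channels(self):
        image = np.zeros((10, 10, 3), dtype=np.uint8)
        row = image_feature_row(image, np.zeros((10, 10), bool))
        assert not row.complete
        assert np.isnan(row.gd)
        assert all(cf.integral_area == 0 for cf in row.channels.values())

    def test_integral_areas_equal_without_zero_valued_pixels(self):
        rng = np.random.default_rng(5)
        image = rng.integers(40, 220, (30, 30, 3), dtype=np.uint8)
        mask = rng.random((30, 30)) < 0.5
        row = image_feature_row(image, mask)
        areas = {cf.integral_area for cf in row.channels.values()}
        assert areas == {int(mask.sum())}
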