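"""Tests for Mander's coefficients, puncta detection/classification and profiles."""

import numpy as np
import pytest

from endoquant.coloc_imaging import (
    ChannelImage,
    Roi,
    TwoChannelImage,
    auto_threshold,
    classify_puncta,
    detect_puncta,
    line_profile,
    manders,
    puncta_density,
)
from endoquant.errors import (
    DegenerateThresholdError,
    InvalidParameterError,
    UndefinedCoefficientError,
)
from endoquant.synthetic import gen_coloc_images


def channel(pixels, pixel_size=0.1):
    return ChannelImage(pixels=np.asarray(pixels, dtype=float), pixel_size=pixel_size)


def two_channel(rec, arr, pixel_size=0.1):
    return TwoChannelImage(receptor=channel(rec, pixel_size), arrestin=channel(arr, pixel_size))


class TestManders:
    def test_identical_binary_channels(self):
        px = np.zeros((20, 20))
        px[5:10, 5:10] = 1.0
        img = two_channel(px, px)
        res = manders(img, Roi((0, 0), 20, 0.1), 0.5, 0.5)
        assert res.m1 == 1.0 and res.m2 == 1.0

    def test_disjoint_binary_channels(self):
        rec = np.zeros((20, 20))
        arr = np.zeros((20, 20))
        rec[2:6, 2:6] = 1.0
        arr[12:16, 12:16] = 1.0
        res = manders(two_channel(rec, arr), Roi((0, 0), 20, 0.1), 0.5, 0.5)
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_half_overlap_pixel_count(self):
        rec = np.zeros((10, 10))
        arr = np.zeros((10, 10))
        rec[2:6, 2:6] = 1.0  # uniform region R, 16 px
        arr[2:6, 2:4] = 1.0  # exactly half of R
        res = manders(two_channel(rec, arr), Roi((0, 0), 10, 0.1), 0.5, 0.5)
        assert res.m1 == pytest.approx(0.5)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        rec = rng.uniform(0, 1, (30, 30))
        arr = rng.uniform(0, 1, (30, 30))
        img = two_channel(rec, arr)
        base = manders(img, Roi((0, 0), 30, 0.1), 0.4, 0.6)
        scaled = manders(two_channel(7.0 * rec, 3.0 * arr), Roi((0, 0), 30, 0.1),
                         7.0 * 0.4, 3.0 * 0.6)
        assert scaled.m1 == pytest.approx(base.m1)
        assert scaled.m2 == pytest.approx(base.m2)

    def test_no_signal_raises(self):
        img = two_channel(np.zeros((10, 10)), np.ones((10, 10)))
        with pytest.raises(UndefinedCoefficientError):
            manders(img, Roi((0, 0), 10, 0.1), 0.5, 0.5)

    def test_roi_out_of_bounds(self):
        px = np.ones((10, 10))
        img = two_channel(px, px)
        with pytest.raises(InvalidParameterError):
            manders(img, Roi((5, 5), 10, 0.1), 0.5, 0.5)


class TestAutoThreshold:
    def test_two_level_otsu(self):
        px = np.zeros((20, 20))
        px[:5] = 100.0
        thr = auto_threshold(channel(px), "otsu")
        assert 0.0 < thr < 100.0

    def test_mean_plus_k_sd_moments(self, rng):
        px = np.clip(rng.normal(10.0, 2.0, (100, 100)), 0, None)
        thr = auto_threshold(channel(px), "mean_plus_k_sd", k=2.0)
        assert thr == pytest.approx(px.mean() + 2 * px.std(), rel=1e-12)
        assert thr == pytest.approx(14.0, abs=0.5)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            auto_threshold(channel(np.full((10, 10), 3.0)))


class TestDetectPuncta:
    def test_single_square(self):
        px = np.zeros((20, 20))
        px[4:7, 4:7] = 1.0
        puncta = detect_puncta(channel(px, 0.1), 0.5, min_area=0.05)
        assert len(puncta) == 1
        assert puncta.puncta[0].area == pytest.approx(0.09)
        assert puncta.puncta[0].centroid == (5.0, 5.0)

    def test_empty_mask(self):
        puncta = detect_puncta(channel(np.zeros((10, 10)), 0.1), 0.5, min_area=0.0)
        assert len(puncta) == 0

    def test_corner_touching_is_single_component(self):
        px = np.zeros((10, 10))
        px[2:4, 2:4] = 1.0
        px[4:6, 4:6] = 1.0  # touches only at corner (3,3)-(4,4)
        puncta = detect_puncta(channel(px, 0.1), 0.5, min_area=0.0)
        assert len(puncta) == 1

    def test_min_area_filter(self):
        px = np.zeros((20, 20))
        px[2, 2] = 1.0  # single pixel: 0.01 um^2
        px[10:13, 10:13] = 1.0  # 9 px: 0.09 um^2
        puncta = detect_puncta(channel(px, 0.1), 0.5, min_area=0.05)
        assert len(puncta) == 1


class TestClassifyPuncta:
    @staticmethod
    def receptor_with_two_puncta():
        px = np.zeros((30, 30))
        px[3:6, 3:6] = 1.0
        px[20:23, 20:23] = 1.0
        return channel(px, 0.1)

    def test_zero_arrestin_all_receptor_only(self):
        rec = self.receptor_with_two_puncta()
        puncta = detect_puncta(rec, 0.5, 0.0)
        counts = classify_puncta(puncta, channel(np.zeros((30, 30)), 0.1), 0.5)
        assert counts == (2, 0)

    def test_identical_channels_all_double_positive(self):
        rec = self.receptor_with_two_puncta()
        puncta = detect_puncta(rec, 0.5, 0.0)
        counts = classify_puncta(puncta, rec, 0.5)
        assert counts == (0, 2)

    def test_counts_partition(self):
        img, _ = gen_coloc_images(30, 0.5, seed=5)
        thr = auto_threshold(img.receptor, "mean_plus_k_sd")
        puncta = detect_puncta(img.receptor, thr, 0.02)
        n_only, n_double = classify_puncta(
            puncta, img.arrestin, auto_threshold(img.arrestin, "mean_plus_k_sd")
        )
        assert n_only + n_double == len(puncta)


class TestPunctaDensity:
    def test_counts_per_100_um2(self):
        px = np.zeros((120, 120))
        rng = np.random.default_rng(3)
        rows = rng.choice(np.arange(5, 95, 9), 10, replace=False)
        for r in rows[:5]:
            px[r : r + 2, r : r + 2] = 1.0
        puncta = detect_puncta(channel(px, 1.0), 0.5, 0.0)
        roi_100 = Roi((0, 0), 100, 1.0)  # 100x100 px at 1 um/px -> 10000 um^2
        assert puncta_density(puncta, roi_100) == pytest.approx(len(puncta) * 100 / 10000)

    def test_scaling_arithmetic(self):
        # 5 puncta inside a 50 um^2 ROI -> 10 per 100 um^2
        px = np.zeros((100, 100))
        for i in range(5):
            px[10 + 10 * i, 10] = 1.0
        pixel_size = 50**0.5 / 70  # ROI side 70 px -> area exactly 50 um^2
        puncta = detect_puncta(channel(px, pixel_size), 0.5, 0.0)
        roi = Roi((0, 0), 70, pixel_size)
        assert roi.area == pytest.approx(50.0)
        assert puncta_density(puncta, roi) == pytest.approx(10.0)

    def test_empty_roi(self):
        puncta = detect_puncta(channel(np.zeros((20, 20)), 0.1), 0.5, 0.0)
        assert puncta_density(puncta, Roi((0, 0), 20, 0.1)) == 0.0


class TestLineProfile:
    def test_constant_image(self):
        img = two_channel(np.full((20, 20), 2.0), np.full((20, 20), 3.0))
        prof = line_profile(img, (0, 0), (19, 19), 10)
        assert np.allclose(prof["receptor_AU"], 2.0)
        assert np.allclose(prof["arrestin_AU"], 3.0)

    def test_linear_ramp(self):
        ramp = np.tile(np.arange(20, dtype=float), (20, 1))
        img = two_channel(ramp, ramp)
        prof = line_profile(img, (10, 0), (10, 19), 20)
        assert np.allclose(np.diff(prof["receptor_AU"]), 1.0)
        assert prof["distance_um"].iloc[-1] == pytest.approx(19 * 0.1)

    def test_gaussian_spot_peak_position(self):
        rows, cols = np.mgrid[0:41, 0:41]
        spot = np.exp(-((rows - 20.0) ** 2 + (cols - 23.0) ** 2) / (2 * 2.0**2))
        img = two_channel(spot, spot)
        n = 81
        prof = line_profile(img, (20, 0), (20, 40), n)
        peak_col = prof["receptor_AU"].idxmax() * 40 / (n - 1)
        assert abs(peak_col - 23.0) <= 40 / (n - 1)

    def test_out_of_bounds_endpoint(self):
        img = two_channel(np.ones((10, 10)), np.ones((10, 10)))
        with pytest.raises(InvalidParameterError):
            line_profile(img, (0, 0), (15, 5), 5)
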