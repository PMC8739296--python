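"""Unit tests for the CARS lipid-body detection chain."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from eosiquant import cars
from eosiquant.cars import (
    CarsDetectionConfig,
    detect_lipid_bodies,
    fft_bandpass,
    filter_particles,
    invert_and_quantize,
    laplacian_of_gaussian,
    renyi_threshold_value,
    subtract_background_rolling_ball,
    threshold_relative_mean,
)
from eosiquant.image import IntensityImage
from eosiquant.synthetic import _add_gaussian_spot


def _ball_opening(pixels: np.ndarray, radius: float) -> np.ndarray:
    """Independent rolling-ball oracle: grayscale opening with a ball element."""
    size = 2 * int(radius) + 1
    yy, xx = np.mgrid[:size, :size] - int(radius)
    r2 = radius**2 - yy**2 - xx**2
    inside = r2 >= 0
    ball = np.full((size, size), -np.inf)
    ball[inside] = np.sqrt(r2[inside])
    eroded = ndi.grey_erosion(pixels, structure=ball)
    return ndi.grey_dilation(eroded, structure=ball)


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        img = IntensityImage(np.full((30, 30), 100.0))
        out = subtract_background_rolling_ball(img, radius=3)
        assert np.allclose(out.pixels, 0.0, atol=1e-6)

    def test_isolated_spike_retained(self):
        pixels = np.full((21, 21), 10.0)
        pixels[10, 10] = 200.0
        out = subtract_background_rolling_ball(IntensityImage(pixels), radius=3)
        assert out.pixels[10, 10] == pytest.approx(190.0, abs=5.0)
        # matches the opening oracle
        oracle = pixels - _ball_opening(pixels, 3)
        assert out.pixels[10, 10] == pytest.approx(oracle[10, 10], abs=3.0)

    def test_shallow_ramp_mostly_removed(self):
        yy, xx = np.mgrid[:40, :40]
        pixels = 0.05 * xx  # slope << 1/radius
        out = subtract_background_rolling_ball(IntensityImage(pixels), radius=3)
        rng_range = pixels.max() - pixels.min()
        assert np.abs(out.pixels).max() < 0.05 * rng_range

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            IntensityImage(np.array([[1.0, np.nan], [0.0, 0.0]]))

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            subtract_background_rolling_ball(IntensityImage(np.ones((5, 5))), radius=0.5)


class TestLaplacianOfGaussian:
    def test_constant_gives_zero(self):
        out = laplacian_of_gaussian(IntensityImage(np.full((20, 20), 7.0)))
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_blob_center_is_negative_minimum(self):
        pixels = np.zeros((41, 41))
        _add_gaussian_spot(pixels, 20, 20, sigma=3.0, amplitude=100.0)
        out = laplacian_of_gaussian(IntensityImage(pixels), smoothing_scale=1.0)
        assert np.unravel_index(np.argmin(out.pixels), out.pixels.shape) == (20, 20)
        assert out.pixels[20, 20] < 0

    def test_matches_explicit_kernel_convolution(self):
        rng = np.random.default_rng(3)
        pixels = rng.random((32, 32))
        out = laplacian_of_gaussian(IntensityImage(pixels), smoothing_scale=1.0)
        # oracle: truncated Gaussian kernel convolution then 4-neighbour Laplacian stencil
        x = np.arange(-8, 9)
        g = np.exp(-(x**2) / 2.0)
        g /= g.sum()
        sm = ndi.convolve(ndi.convolve(pixels, g[None, :], mode="nearest"), g[:, None], mode="nearest")
        lap_kernel = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
        oracle = ndi.convolve(sm, lap_kernel, mode="nearest")
        interior = (slice(4, -4), slice(4, -4))
        assert np.allclose(out.pixels[interior], oracle[interior], atol=1e-5)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        pixels = rng.random((16, 16))
        a = laplacian_of_gaussian(IntensityImage(2.0 * pixels)).pixels
        b = 2.0 * laplacian_of_gaussian(IntensityImage(pixels)).pixels
        assert np.allclose(a, b, atol=1e-9)


class TestFftBandpass:
    @staticmethod
    def _sinusoid(period: float, shape=(120, 120)) -> np.ndarray:
        xx = np.arange(shape[1])[None, :] * np.ones((shape[0], 1))
        return np.sin(2 * np.pi * xx / period)

    def test_constant_dc_removed(self):
        out = fft_bandpass(IntensityImage(np.full((64, 64), 42.0)))
        assert np.abs(out.pixels).max() < 1e-9

    def test_in_band_period_preserved(self):
        sig = self._sinusoid(8.0)
        out = fft_bandpass(IntensityImage(sig), 2, 20)
        assert out.pixels.max() == pytest.approx(1.0, rel=0.10)

    def test_out_of_band_period_attenuated(self):
        sig = self._sinusoid(60.0)
        out = fft_bandpass(IntensityImage(sig), 2, 20)
        assert np.abs(out.pixels).max() < 0.10

    def test_zero_mean_preserved(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((64, 64))
        sig -= sig.mean()
        out = fft_bandpass(IntensityImage(sig))
        assert abs(out.pixels.mean()) < 1e-9

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ValueError):
            fft_bandpass(IntensityImage(np.ones((32, 32))), 20, 2)


class TestInvertAndQuantize:
    def test_endpoints(self):
        pixels = np.linspace(0, 1, 16).reshape(4, 4)
        out = invert_and_quantize(IntensityImage(pixels))
        assert out.pixels[0, 0] == 255  # min maps to 255
        assert out.pixels[-1, -1] == 0  # max maps to 0
        assert out.bit_depth == "8-bit"

    def test_two_level_image(self):
        out = invert_and_quantize(IntensityImage(np.array([[0.0, 1.0]])))
        assert list(out.pixels[0]) == [255, 0]

    def test_involution_on_8bit_result(self):
        rng = np.random.default_rng(2)
        img8 = invert_and_quantize(IntensityImage(rng.random((20, 20))))
        twice = invert_and_quantize(invert_and_quantize(img8))
        assert np.array_equal(twice.pixels, img8.pixels)

    def test_constant_input_all_zero(self):
        out = invert_and_quantize(IntensityImage(np.full((5, 5), 3.3)))
        assert np.all(out.pixels == 0)
        assert "quantize_note" in out.meta


def _renyi_oracle(img8: np.ndarray) -> int:
    """Independent brute-force scan of the three-order Renyi criterion."""
    hist = np.bincount(np.asarray(img8, dtype=np.uint8).ravel(), minlength=256)
    p = hist / hist.sum()
    P1 = np.cumsum(p)

    def argmax_alpha(alpha):
        best, best_phi = 0, -np.inf
        for t in range(256):
            pb, pw = P1[t], 1.0 - P1[t]
            if pb < 1e-12 or pw < 1e-12:
                continue
            back = [p[i] / pb for i in range(t + 1) if p[i] > 0]
            fore = [p[i] / pw for i in range(t + 1, 256) if p[i] > 0]
            if alpha == 1.0:
                phi = -sum(q * math.log(q) for q in back) - sum(q * math.log(q) for q in fore)
            else:
                phi = (math.log(sum(q**alpha for q in back)) + math.log(sum(q**alpha for q in fore))) / (1 - alpha)
            if phi > best_phi:
                best_phi, best = phi, t
        return best

    t1, t2, t3 = sorted(argmax_alpha(a) for a in (0.5, 1.0, 2.0))
    if abs(t1 - t3) <= 5:
        b1, b2, b3 = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b1, b2, b3 = (0, 1, 3) if abs(t2 - t3) <= 5 else (3, 1, 0)
    omega = P1[t3] - P1[t1]
    return int(t1 * (P1[t1] + 0.25 * omega * b1) + 0.25 * t2 * omega * b2 + t3 * ((1 - P1[t3]) + 0.25 * omega * b3))


class TestRenyiThreshold:
    def test_matches_bruteforce_oracle_on_random_images(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            img = rng.integers(0, 256, size=(40, 40), dtype=np.uint8)
            assert renyi_threshold_value(img) == _renyi_oracle(img)

    def test_bimodal_separation(self):
        img = np.array([[50] * 12 + [200] * 6], dtype=np.uint8)
        t = renyi_threshold_value(img)
        assert 50 <= t < 200
        fore = img > t
        assert fore.sum() == 6 and np.all(img[fore] == 200)

    def test_histogram_shift_property(self):
        rng = np.random.default_rng(12)
        img = rng.integers(40, 140, size=(30, 30), dtype=np.uint8)
        shifted = (img + 50).astype(np.uint8)  # no clipping: max 189 + 50 < 256
        assert renyi_threshold_value(shifted) == renyi_threshold_value(img) + 50

    def test_single_valued_image_fails(self):
        with pytest.raises(ValueError):
            renyi_threshold_value(np.full((10, 10), 7, dtype=np.uint8))


class TestRelativeMeanThreshold:
    def test_constant_image_empty_foreground(self):
        mask = threshold_relative_mean(IntensityImage(np.full((8, 8), 100.0)), factor=1.4)
        assert not mask.any()

    def test_strict_inequality_at_threshold(self):
        # mean 50 -> threshold 70: 71 is foreground, 69 and 70 are not
        pixels = np.array([[29.0, 31.0, 69.0, 70.0, 71.0, 30.0]])
        pixels = pixels - pixels.mean() + 50.0
        mask = threshold_relative_mean(IntensityImage(pixels), factor=1.4)
        assert list(mask[0]) == [False, False, False, False, True, False]

    def test_checkerboard(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 200.0
        mask = threshold_relative_mean(IntensityImage(board), factor=1.4)
        assert np.array_equal(mask, board == 200.0)


def _disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:size, :size] - (radius + pad)
    return (yy**2 + xx**2) <= radius**2


class TestFilterParticles:
    def test_disk_retained(self):
        spots = filter_particles(_disk_mask(5))
        assert spots.count == 1
        assert 3.15 < spots.spots[0].area < 314.2
        assert spots.spots[0].circularity > 0.8

    def test_thin_line_excluded_by_circularity(self):
        mask = np.zeros((10, 40), dtype=bool)
        mask[5, 5:35] = True
        spots = filter_particles(mask)
        assert spots.count == 0
        assert spots.excluded[0][1] == "circularity"

    def test_two_pixel_blob_excluded_by_area(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3:5] = True  # area 2 < pi
        spots = filter_particles(mask)
        assert spots.count == 0
        assert spots.excluded[0][1] == "area_small"

    def test_huge_blob_excluded_by_area(self):
        spots = filter_particles(_disk_mask(30, pad=4))
        assert spots.count == 0
        assert spots.excluded[0][1] == "area_large"

    def test_empty_image_gives_empty_set(self):
        assert filter_particles(np.zeros((10, 10), dtype=bool)).count == 0

    def test_raising_min_circularity_never_increases_count(self):
        rng = np.random.default_rng(8)
        mask = rng.random((60, 60)) > 0.7
        counts = [filter_particles(mask, min_circularity=c).count for c in (0.0, 0.3, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestDetectLipidBodies:
    def test_blank_image_gives_zero_spots(self):
        img = IntensityImage(np.full((64, 64), 120, dtype=np.uint16))
        assert detect_lipid_bodies(img, CarsDetectionConfig(threshold_mode="relative_mean")).count == 0

    def test_oversized_blob_rejected_by_size_gate(self):
        pixels = np.full((161, 161), 100.0)
        _add_gaussian_spot(pixels, 80, 80, sigma=15.0, amplitude=5000.0)  # 30 px radius
        img = IntensityImage(np.clip(pixels, 0, 65535).astype(np.uint16))
        spots = detect_lipid_bodies(img, CarsDetectionConfig(threshold_mode="relative_mean"))
        assert spots.count == 0

    @pytest.mark.parametrize("mode", ["relative_mean", "renyi"])
    def test_high_snr_recall_and_precision(self, cars_scene, mode):
        """>= 95% recall and precision on isolated in-gate LBs (n > 100)."""
        (cars_img, _), truth = cars_scene
        assert truth.n_lbs >= 40
        spots = detect_lipid_bodies(cars_img, CarsDetectionConfig(threshold_mode=mode))
        det = np.array([(s.centroid[1], s.centroid[0]) for s in spots.spots])
        gt = np.array([r.center for r in truth.lb_records])
        d_rec, _ = cKDTree(det).query(gt)
        d_prec, _ = cKDTree(gt).query(det)
        assert (d_rec < 6).mean() >= 0.95
        assert (d_prec < 6).mean() >= 0.95

    def test_provenance_recorded(self, cars_scene):
        (cars_img, _), _ = cars_scene
        spots = detect_lipid_bodies(cars_img, CarsDetectionConfig(threshold_mode="renyi"))
        for key in ("ball_radius", "log_scale", "bandpass_small", "threshold_mode", "min_circularity"):
            assert key in spots.filter_params

    def test_unknown_threshold_mode_rejected(self, cars_scene):
        (cars_img, _), _ = cars_scene
        with pytest.raises(ValueError):
            detect_lipid_bodies(cars_img, CarsDetectionConfig(threshold_mode="otsu"))
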