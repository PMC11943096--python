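"""The three-step noise-injection pipeline and its auto-factor search."""

import numpy as np
import pytest

from lowdose.calibration import measured_noise_slope
from lowdose.ingen import (
    SimulationConfig,
    apply_and_restore,
    build_noise_mask,
    estimate_factor,
    refine_noise_mask,
    simulate_low_dose,
    threshold_windows,
)
from lowdose.phantom_model import SyntheticPhantomSpec, generate_phantom
from lowdose.radiograph import Radiograph


class TestThresholdWindows:
    def test_constant_image_is_a_single_window(self):
        part = threshold_windows(np.full((8, 8), 42.0), 20)
        assert part.shape == (8, 8) and np.all(part == 0)

    def test_bin_width_follows_occupied_range(self):
        # values 0..99, 20 bins -> width 4.95; value 12 -> floor(12/4.95) = 2
        img = np.arange(100, dtype=float).reshape(10, 10)
        part = threshold_windows(img, 20)
        assert part[1, 2] == 2  # pixel value 12
        assert part[0, 0] == 0 and part[9, 9] == 19  # max is in the closed last bin

    def test_every_pixel_gets_exactly_one_bin(self, rng):
        img = rng.integers(0, 65535, size=(50, 50)).astype(float)
        part = threshold_windows(img, 20)
        assert part.min() >= 0 and part.max() <= 19

    def test_default_bin_count_is_twenty(self):
        assert SimulationConfig().n_thresholds == 20

    def test_full_range_option_uses_bit_depth(self):
        img = Radiograph(np.full((64, 64), 1000, dtype=np.uint16))
        part = threshold_windows(img, 20, full_range=True)
        # 1000 / (65535/20) = 0.305... -> bin 0
        assert np.all(part == 0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            threshold_windows(np.zeros((8, 8)), 1)


class TestBuildNoiseMask:
    def test_zero_slope_gives_zero_mask(self, rng):
        img = rng.integers(0, 100, (32, 32)).astype(float)
        mask = build_noise_mask(img, threshold_windows(img, 20), 0.0, rng)
        assert np.all(mask == 0)

    def test_single_window_moments(self):
        # constant image: one window of mean m; mask ~ Uniform(-m*s, m*s)
        m, s = 500.0, 0.02
        img = np.full((512, 512), m)
        mask = build_noise_mask(img, threshold_windows(img, 20), s, rng=99)
        assert np.abs(mask).max() <= m * s
        assert abs(mask.mean()) < m * s * 0.01
        assert mask.std() == pytest.approx(m * s / np.sqrt(3), rel=0.02)

    def test_same_seed_reproduces_the_mask(self, rng):
        img = rng.integers(0, 1000, (64, 64)).astype(float)
        part = threshold_windows(img, 20)
        a = build_noise_mask(img, part, 0.01, np.random.default_rng(5))
        b = build_noise_mask(img, part, 0.01, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            build_noise_mask(np.zeros((10, 10)), np.zeros((5, 5), dtype=int), 0.01, 0)


class TestRefineNoiseMask:
    def test_zero_mask_stays_zero(self):
        out = refine_noise_mask(np.zeros((16, 16)), 9.0, 1.0)
        assert np.all(out == 0)

    def test_factor_six_without_smoothing_is_exact_scaling(self, rng):
        mask = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(refine_noise_mask(mask, 6.0, 0.0), mask * 6.0)

    def test_impulse_response_matches_explicit_gaussian_kernel(self):
        # brute-force oracle: normalised truncated Gaussian, radius 4 at sigma 1
        sigma, radius = 1.0, 4
        x = np.arange(-radius, radius + 1, dtype=float)
        k1 = np.exp(-0.5 * x**2 / sigma**2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        mask = np.zeros((17, 17))
        mask[8, 8] = 1.0
        out = refine_noise_mask(mask, 1.0, sigma)
        np.testing.assert_allclose(out[4:13, 4:13], kernel, atol=1e-12)

    def test_linearity_superposition(self, rng):
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        lhs = refine_noise_mask(a + b, 6.0, 1.0)
        rhs = refine_noise_mask(a, 6.0, 1.0) + refine_noise_mask(b, 6.0, 1.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            refine_noise_mask(np.zeros((4, 4)), 0.0, 1.0)
        with pytest.raises(ValueError):
            refine_noise_mask(np.zeros((4, 4)), 6.0, -1.0)


class TestApplyAndRestore:
    def test_zero_mask_is_identity(self, rng):
        img = Radiograph(rng.integers(0, 65535, (32, 32)).astype(np.uint16))
        out = apply_and_restore(img, np.zeros((32, 32)))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_range_is_restored_exactly(self, rng):
        img = Radiograph(rng.integers(100, 60000, (64, 64)).astype(np.uint16))
        mask = rng.normal(0, 500, (64, 64))
        out = apply_and_restore(img, mask, "minmax")
        assert out.pixels.min() == img.pixels.min()
        assert out.pixels.max() == img.pixels.max()

    def test_worked_affine_example(self):
        # input range [0, 100]; mask pushes the range to [-10, 110]; the
        # restore map is x -> (x + 10) * 100 / 120, applied then rounded
        pixels = np.array(
            [[0, 100, 50, 20], [80, 30, 60, 10], [90, 40, 70, 5], [15, 25, 35, 45]],
            dtype=np.uint8,
        )
        img = Radiograph(pixels, bit_depth=8)
        mask = np.zeros((4, 4))
        mask[0, 0] = -10.0  # noisy min -10
        mask[0, 1] = 10.0  # noisy max 110
        mask[1, 0] = 5.0
        out = apply_and_restore(img, mask, "minmax")
        noisy = pixels.astype(float) + mask
        expected = np.rint((noisy + 10.0) * 100.0 / 120.0).astype(np.uint8)
        np.testing.assert_array_equal(out.pixels, expected)

    def test_histogram_mode_preserves_range_and_distribution_shape(self, rng):
        img = Radiograph(rng.integers(0, 4000, (64, 64)).astype(np.uint16))
        mask = rng.normal(0, 50, (64, 64))
        out = apply_and_restore(img, mask, "histogram")
        assert out.pixels.min() >= img.pixels.min()
        assert out.pixels.max() <= img.pixels.max()
        # matched histograms: quantiles agree closely
        q = np.quantile(out.pixels, [0.25, 0.5, 0.75])
        q0 = np.quantile(img.pixels, [0.25, 0.5, 0.75])
        np.testing.assert_allclose(q, q0, rtol=0.02)

    def test_shape_mismatch_is_an_error(self):
        img = Radiograph(np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="shape"):
            apply_and_restore(img, np.zeros((4, 4)))


class TestSimulateLowDose:
    def test_auto_factor_hits_the_goal_slope(self, phantom512, cal_100):
        sim = simulate_low_dose(
            phantom512, cal_100, SimulationConfig(dose_fraction=0.5, seed=7)
        )
        goal = sim.meta["goal_slope"]
        achieved = measured_noise_slope(sim)
        assert abs(achieved - goal) / goal < 0.10

    def test_noise_ordering_with_dose(self, phantom512, cal_100):
        s_orig = measured_noise_slope(phantom512)
        slopes = {}
        for dose in (0.5, 0.25):
            sim = simulate_low_dose(
                phantom512, cal_100, SimulationConfig(dose_fraction=dose, seed=3)
            )
            slopes[dose] = measured_noise_slope(sim)
        assert slopes[0.25] > slopes[0.5] > s_orig

    def test_bitwise_determinism(self, phantom512, cal_100):
        cfg = SimulationConfig(dose_fraction=0.5, seed=11)
        a = simulate_low_dose(phantom512, cal_100, cfg)
        b = simulate_low_dose(phantom512, cal_100, cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.meta["factor"] == b.meta["factor"]

    def test_full_dose_goal_is_a_near_identity_perturbation(self, phantom512, cal_100):
        # goal slope == the image's own dose level: the minimal factor
        # perturbation barely moves the measured slope
        s_orig = measured_noise_slope(phantom512)
        sim = simulate_low_dose(
            phantom512, cal_100, SimulationConfig(dose_fraction=1.0, seed=1)
        )
        assert measured_noise_slope(sim) == pytest.approx(s_orig, rel=0.10)

    def test_provenance_metadata_recorded(self, phantom512, cal_100):
        cfg = SimulationConfig(dose_fraction=0.25, seed=5)
        sim = simulate_low_dose(phantom512, cal_100, cfg)
        assert sim.meta["dose_fraction"] == 0.25
        assert sim.meta["seed"] == 5
        assert sim.meta["factor"] > 0
        assert sim.meta["restore_mode"] == "minmax"

    def test_named_factor_is_used_verbatim(self, phantom512, cal_100):
        sim = simulate_low_dose(
            phantom512, cal_100, SimulationConfig(factor=6.0, dose_fraction=0.5, seed=2)
        )
        assert sim.meta["factor"] == 6.0

    def test_inverted_photometric_round_trip(self, phantom512, cal_100):
        cfg = SimulationConfig(dose_fraction=0.5, seed=13)
        flipped = Radiograph(
            (phantom512.peak - phantom512.pixels).astype(np.uint16),
            phantom512.bit_depth,
            "inverted",
            dict(phantom512.meta),
        )
        sim_inv = simulate_low_dose(flipped, cal_100, cfg)
        sim_std = simulate_low_dose(phantom512, cal_100, cfg)
        assert sim_inv.photometric == "inverted"
        np.testing.assert_array_equal(
            sim_inv.pixels, phantom512.peak - sim_std.pixels.astype(int)
        )

    def test_small_image_rejected(self, cal_100):
        img = Radiograph(np.zeros((32, 32), dtype=np.uint16), meta={"kvp": 100, "mas": 2})
        with pytest.raises(ValueError, match="64"):
            simulate_low_dose(img, cal_100)

    def test_missing_acquisition_metadata_rejected(self, cal_100):
        img = Radiograph(np.zeros((128, 128), dtype=np.uint16))
        with pytest.raises(ValueError, match="kvp"):
            simulate_low_dose(img, cal_100)


class TestEstimateFactor:
    def test_errors_when_goal_not_above_current(self, phantom512):
        current = measured_noise_slope(phantom512)
        with pytest.raises(ValueError, match="already at or below"):
            estimate_factor(phantom512, current * 0.5)

    def test_monotone_in_goal_slope(self, phantom512, cal_100):
        from lowdose.calibration import goal_slope

        kvp, mas = phantom512.meta["kvp"], phantom512.meta["mas"]
        g50 = goal_slope(cal_100, kvp, mas, 0.5)
        g25 = goal_slope(cal_100, kvp, mas, 0.25)
        f50 = estimate_factor(phantom512, g50)
        f25 = estimate_factor(phantom512, g25)
        assert f25 > f50
        # hand-tuned factors in this problem domain are single digits;
        # log for inspection, assert only a loose sanity band
        assert 1.0 <= f50 <= 20.0 and 1.0 <= f25 <= 20.0
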