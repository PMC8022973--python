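"""Per-worm pixel scoring: image ops, calibration, group comparison."""

import numpy as np
import pytest
from conftest import brute_force_score
from sklearn.base import clone

from nemaquant.fluorescence import (
    BoundingBox,
    FluorescenceScore,
    FluorescenceScorer,
    QuantConfig,
    adjust_bci,
    calibrate_variance,
    compare_fluorescence,
    count_bright_pixels,
    crop,
    estimate_background,
    invert,
    process_worm,
    score_worm,
)
from nemaquant.simulate import ImageSimParams, generate_worm_image
from nemaquant.stats import mann_whitney_u

IDENTITY = QuantConfig(brightness_pct=0, contrast_pct=0, intensity_pct=0)


def checkerboard(h, w, lo=50, hi=200):
    img = np.full((h, w), lo, np.uint8)
    img[::2, ::2] = hi
    return img


class TestImageOps:
    def test_full_image_crop_is_identity(self):
        img = checkerboard(6, 8)
        assert np.array_equal(crop(img, BoundingBox.full(img)), img)

    def test_half_open_crop_arithmetic(self):
        img = checkerboard(10, 10)
        assert crop(img, BoundingBox(2, 2, 5, 5)).shape == (3, 3)

    def test_crop_composition(self, rng):
        img = rng.integers(0, 256, (30, 40)).astype(np.uint8)
        once = crop(img, BoundingBox(7, 4, 27, 19))
        twice = crop(crop(img, BoundingBox(5, 2, 30, 25)), BoundingBox(2, 2, 22, 17))
        assert np.array_equal(once, twice)

    def test_out_of_bounds_crop_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            crop(checkerboard(5, 5), BoundingBox(0, 0, 6, 5))

    def test_invert_values_and_involution(self, rng):
        img = rng.integers(0, 256, (12, 9)).astype(np.uint8)
        assert invert(np.array([[0]], np.uint8))[0, 0] == 255
        assert invert(np.array([[0xD1]], np.uint8))[0, 0] == 46
        assert np.array_equal(invert(invert(img)), img)

    def test_adjust_identity_when_zero_percent(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert np.array_equal(adjust_bci(img, IDENTITY), img)

    @pytest.mark.parametrize(
        "pixel, cfg, expected",
        [
            # 100 + 255*(-17)/100 = 56.65 -> rounds half away to 57
            (100, QuantConfig(brightness_pct=-17, contrast_pct=0, intensity_pct=0), 57),
            # contrast pulls 0 far below mid-gray: clamps at 0
            (0, QuantConfig(brightness_pct=0, contrast_pct=71, intensity_pct=0), 0),
            # published triple on the reference gray 0xD1: 209 -> 166 -> 193 -> 141
            (209, QuantConfig(), 141),
        ],
    )
    def test_adjust_hand_arithmetic(self, pixel, cfg, expected):
        out = adjust_bci(np.full((2, 2), pixel, np.uint8), cfg)
        assert int(out[0, 0]) == expected

    @pytest.mark.parametrize(
        "img, expected",
        [
            (np.full((5, 5), 209, np.uint8), 209),
            (np.r_[np.full(99, 209), [255]].reshape(10, 10).astype(np.uint8), 209),
            (np.repeat([100, 200], 50).reshape(10, 10).astype(np.uint8), 200),  # tie -> lighter
        ],
    )
    def test_estimate_background_mode(self, img, expected):
        assert estimate_background(img) == expected

    def test_count_strict_threshold(self):
        img = np.array([[255, 209]], np.uint8)
        assert count_bright_pixels(np.full((3, 3), 209, np.uint8), 209, 0) == 0
        assert count_bright_pixels(img, 209, 40) == 1  # |46| > 40
        assert count_bright_pixels(img, 209, 46) == 0  # strict inequality


class TestScoring:
    def test_score_matches_brute_force_on_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (25, 35)).astype(np.uint8)
            box = BoundingBox(3, 2, 33, 22)
            cfg = QuantConfig(variance=int(rng.integers(0, 120)))
            got = score_worm(img, box, cfg)
            assert got.bright_pixel_count == brute_force_score(img, box, cfg)
            assert got.total_pixels == 30 * 20

    def test_scoring_is_deterministic(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        a = score_worm(img, cfg=QuantConfig())
        b = score_worm(img, cfg=QuantConfig())
        assert a == b

    def test_calibrated_noiseless_control_scores_zero(self):
        """A flat control at the calibrated background never counts pixels."""
        control = np.full((30, 30), 120, np.uint8)
        processed = adjust_bci(invert(control), QuantConfig())
        bg = estimate_background(processed)
        v = calibrate_variance([processed] * 3, background_gray=bg, target_fraction=0.0)
        assert count_bright_pixels(processed, bg, v) == 0

    def test_uniform_body_increment_never_decreases_count(self):
        """Brighter reporter signal can only add counted pixels (no clamp)."""
        params = ImageSimParams(noise_sd=0, reporter_extra=40)
        cfg = QuantConfig(variance=60, background_gray=186)
        truth = generate_worm_image(params, seed=7)
        counts = []
        for extra in (40, 60, 80, 100):
            t = generate_worm_image(
                ImageSimParams(noise_sd=0, reporter_extra=extra), seed=7
            )
            counts.append(score_worm(t.image, cfg=cfg).bright_pixel_count)
        assert truth.body_mask.any()
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestCalibration:
    def test_controls_at_background_give_zero_variance(self):
        imgs = [np.full((10, 10), 186, np.uint8)] * 3
        assert calibrate_variance(imgs, background_gray=186) == 0

    def test_max_deviation_thirty_calibrates_to_thirty(self):
        img = np.full((10, 10), 100, np.uint8)
        img[0, :3] = 130  # deviation exactly 30
        v = calibrate_variance([img] * 3, background_gray=100, target_fraction=0.0)
        assert v == 30  # strict '>' means deviation 30 is not counted at v = 30

    def test_variance_monotone_in_target_fraction(self, rng):
        imgs = [rng.integers(80, 160, (20, 20)).astype(np.uint8) for _ in range(5)]
        fractions = [0.2, 0.1, 0.05, 0.01, 0.0]
        vs = [
            calibrate_variance(imgs, background_gray=120, target_fraction=f)
            for f in fractions
        ]
        assert all(b >= a for a, b in zip(vs, vs[1:]))

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            calibrate_variance([])


class TestGroupComparison:
    def mk(self, counts):
        return [
            FluorescenceScore(f"w{i}", c, 1000, QuantConfig()) for i, c in enumerate(counts)
        ]

    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="identical"):
            cmp = compare_fluorescence(self.mk([5, 5]), self.mk([5, 5]))
        assert cmp.fold_change == 1.0
        assert cmp.p_value == 1.0

    def test_fold_change_ratio_of_means(self):
        cmp = compare_fluorescence(self.mk([39, 39]), self.mk([10, 10]))
        assert cmp.fold_change == pytest.approx(3.9)

    def test_p_matches_exact_enumeration(self):
        t, c = [7, 9, 11], [1, 2, 3]
        cmp = compare_fluorescence(self.mk(t), self.mk(c))
        ref = mann_whitney_u(t, c)
        assert cmp.p_value == ref.p_value
        assert cmp.method == "exact"

    def test_zero_control_mean_flags_fold(self):
        with pytest.warns(UserWarning, match="fold"):
            cmp = compare_fluorescence(self.mk([4, 5]), self.mk([0, 0]))
        assert cmp.fold_change is None

    def test_treated_separate_from_control_across_seeds(self):
        """Reporter signal well above the calibrated threshold separates the
        groups in every replicate at n = 20 vs 20."""
        significant = 0
        for seed in range(10):
            controls = [
                generate_worm_image(ImageSimParams(), seed=seed, stream_key=10_000 + i).image
                for i in range(20)
            ]
            treated = [
                generate_worm_image(
                    ImageSimParams(reporter_extra=80), seed=seed, stream_key=i
                ).image
                for i in range(20)
            ]
            scorer = FluorescenceScorer().fit(controls)
            cmp = compare_fluorescence(
                list(scorer.transform(treated)), list(scorer.transform(controls))
            )
            significant += cmp.p_value < 0.05 and cmp.fold_change > 1
        assert significant >= 9


class TestScorerEstimator:
    def test_sklearn_params_roundtrip(self):
        s = FluorescenceScorer(variance=30, background_gray=209)
        assert clone(s).get_params() == s.get_params()

    def test_fixed_params_need_no_calibration_data(self):
        s = FluorescenceScorer(variance=40, background_gray=209).fit([])
        img = np.full((5, 5), 0, np.uint8)  # processed value far from 209
        assert s.transform([img]).tolist() == [score_worm(img, cfg=s.config_).bright_pixel_count]

    def test_transform_before_fit_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            FluorescenceScorer().transform([np.zeros((3, 3), np.uint8)])

    def test_fit_calibrates_on_controls(self):
        controls = [
            generate_worm_image(ImageSimParams(), seed=3, stream_key=i).image for i in range(5)
        ]
        s = FluorescenceScorer().fit(controls)
        assert 0 <= s.variance_ <= 255
        assert 0 <= s.background_gray_ <= 255
        # controls score at most the calibration target fraction (median)
        fracs = s.transform(controls) / controls[0].size
        assert np.median(fracs) <= s.target_fraction
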