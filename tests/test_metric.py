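"""The 90-10 transition statistic: normalization, crossings, conversion."""

import numpy as np
import pytest

from filatrans import (
    NoTransitionError,
    Z_90_10,
    analyze_image,
    find_crossings,
    generate_filament_image,
    measure_transition,
    normalize_red,
)
from conftest import clean_spec, profile_from_signal


def gauss_signal(n=400, center=200.0, sigma=10.0):
    from scipy.stats import norm

    x = np.arange(n, dtype=float)
    return norm.sf((x - center) / sigma)


class TestNormalizeRed:
    def test_maps_extremes_to_unit_interval(self):
        profile = profile_from_signal(0.1 + 0.7 * gauss_signal())
        r = normalize_red(profile)
        assert r.max() == 1.0 and r.min() == 0.0

    def test_affine_invariance(self):
        base = gauss_signal()
        r1 = normalize_red(profile_from_signal(0.1 + 0.7 * base))
        r2 = normalize_red(profile_from_signal(0.55 + 0.40 * base))
        assert np.allclose(r1, r2)

    def test_flat_profile_raises(self):
        with pytest.raises(NoTransitionError):
            normalize_red(profile_from_signal(np.full(50, 0.4)))

    def test_gaussian_center_at_half(self, gauss10_image):
        image, truth = gauss10_image
        profile = analyze_image(image, window_px=1)
        r = normalize_red(profile)
        i = np.searchsorted(profile.positions_px, truth.transition_center_px)
        assert r[i] == pytest.approx(0.5, abs=0.01)


class TestFindCrossings:
    def test_unsmoothed_linear_ramp_spans_80_percent(self):
        x = np.arange(300, dtype=float)
        r = np.clip(0.5 - (x - 150.0) / 100.0, 0.0, 1.0)
        start, end = find_crossings(r)
        assert end - start == pytest.approx(80.0, abs=1e-9)

    def test_smoothed_step_spans_16px(self):
        from filatrans import moving_average

        step = np.r_[np.ones(60), np.zeros(60)]
        start, end = find_crossings(moving_average(step, 20))
        assert end - start == pytest.approx(16.0, abs=1e-9)

    def test_degenerate_thresholds_collapse_distance(self):
        r = gauss_signal()
        for eps in (0.05, 0.01, 0.001):
            start, end = find_crossings(r, hi=0.5 + eps, lo=0.5 - eps)
            assert 0 < end - start < 60 * eps

    def test_missing_lower_bound_reported(self):
        r = np.linspace(1.0, 0.5, 50)  # never drops to 0.1
        with pytest.raises(NoTransitionError) as exc:
            find_crossings(r)
        assert exc.value.failed_bound == "lo"

    def test_missing_upper_bound_reported(self):
        r = np.linspace(0.5, 0.0, 50)  # never reaches 0.9 first
        with pytest.raises(NoTransitionError) as exc:
            find_crossings(r)
        assert exc.value.failed_bound == "hi"

    def test_outermost_bracket_under_noise_wiggles(self):
        clean_start, clean_end = find_crossings(gauss_signal())
        r = gauss_signal()
        r[192] = 0.95  # noise spike back above hi inside the transition
        start, end = find_crossings(r)
        # the last >= hi sample before the lo crossing bounds the bracket
        assert start > clean_start and 192.0 <= start < 193.0
        assert end == pytest.approx(clean_end, abs=1e-9)

    def test_reversed_direction_mirror(self):
        r = gauss_signal()
        s1, e1 = find_crossings(r, direction="a_to_b")
        s2, e2 = find_crossings(r[::-1], direction="b_to_a")
        n = len(r)
        assert s2 == pytest.approx((n - 1) - s1)
        assert e2 == pytest.approx((n - 1) - e1)

    def test_pixel_exact_within_one_px_of_subpixel(self):
        r = gauss_signal(sigma=13.3)
        s_sub, e_sub = find_crossings(r)
        s_int, e_int = find_crossings(r, pixel_exact=True)
        assert abs(s_sub - s_int) < 1.0 and abs(e_sub - e_int) < 1.0
        assert s_int == int(s_int) and e_int == int(e_int)


class TestMeasureTransition:
    def test_gaussian_width_in_mm(self, gauss10_image):
        image, truth = gauss10_image
        result = measure_transition(analyze_image(image, window_px=1))
        assert result.distance_mm == pytest.approx(
            truth.true_width_90_10_mm, abs=1.0 * image.mm_per_px
        )
        assert result.distance_px == pytest.approx(
            abs(result.end_px - result.start_px)
        )

    def test_unit_scale_mm_equals_px(self):
        spec = clean_spec(mm_per_px=1.0)
        image, _ = generate_filament_image(spec)
        result = measure_transition(analyze_image(image, window_px=1))
        assert result.distance_mm == result.distance_px
        assert result.uncertainty_mm == 1.0  # pixel quantum dominates the floor

    def test_uncertainty_floor(self, gauss10_image):
        image, _ = gauss10_image  # 0.05 mm/px: floor dominated by pixel size
        result = measure_transition(analyze_image(image, window_px=1))
        assert result.uncertainty_mm == pytest.approx(0.05)
        finer = clean_spec(mm_per_px=0.005)
        res2 = measure_transition(
            analyze_image(generate_filament_image(finer)[0], window_px=1)
        )
        assert res2.uncertainty_mm == pytest.approx(0.02)  # floor kicks in

    def test_resolution_invariance(self):
        coarse = clean_spec(profile_kind="gaussian_cdf", profile_param=10.0)
        fine = clean_spec(
            profile_kind="gaussian_cdf",
            profile_param=20.0,
            mm_per_px=coarse.mm_per_px / 2,
            image_width_px=1600,
            image_height_px=240,
            filament_width_px=80,
            filament_center_row_px=120,
        )
        r_coarse = measure_transition(
            analyze_image(generate_filament_image(coarse)[0], window_px=1)
        )
        r_fine = measure_transition(
            analyze_image(generate_filament_image(fine)[0], window_px=1)
        )
        assert r_fine.distance_px == pytest.approx(2 * r_coarse.distance_px, abs=2.0)
        assert r_fine.distance_mm == pytest.approx(
            r_coarse.distance_mm, abs=coarse.mm_per_px
        )

    def test_color_swap_symmetry(self):
        spec = clean_spec(profile_kind="gaussian_cdf", profile_param=15.0)
        swapped = clean_spec(
            profile_kind="gaussian_cdf", profile_param=15.0,
            color_a=spec.color_b, color_b=spec.color_a,
        )
        d1 = measure_transition(
            analyze_image(generate_filament_image(spec)[0], window_px=1)
        )
        d2 = measure_transition(
            analyze_image(generate_filament_image(swapped)[0], window_px=1)
        )
        assert d1.direction == "a_to_b" and d2.direction == "b_to_a"
        assert abs(d1.distance_px - d2.distance_px) < 1.0

    def test_width_monotone_in_sigma(self):
        widths = []
        for sigma in (5.0, 10.0, 20.0, 40.0):
            spec = clean_spec(profile_kind="gaussian_cdf", profile_param=sigma)
            widths.append(
                measure_transition(
                    analyze_image(generate_filament_image(spec)[0], window_px=1)
                ).distance_px
            )
        assert all(a < b for a, b in zip(widths, widths[1:]))

    @pytest.mark.parametrize("sigma", [5.0, 10.0, 20.0, 40.0])
    @pytest.mark.parametrize("noise", [0.0, 0.01, 0.03])
    def test_parameter_recovery_within_tolerance(self, sigma, noise):
        """Measured width recovers the analytic 90-10 width within 5%
        relative error plus the smoothing-bias allowance of
        0.8 * window * mm_per_px."""
        spec = clean_spec(
            profile_kind="gaussian_cdf", profile_param=sigma,
            noise_sigma=noise, edge_softness_px=1.0, seed=int(sigma),
        )
        image, truth = generate_filament_image(spec)
        result = measure_transition(analyze_image(image, window_px=20))
        allowance = 0.05 * truth.true_width_90_10_mm + 0.8 * 20 * spec.mm_per_px
        assert abs(result.distance_mm - truth.true_width_90_10_mm) <= allowance

    def test_noiseless_window1_recovery_is_subpixel(self):
        spec = clean_spec(profile_kind="gaussian_cdf", profile_param=20.0)
        image, truth = generate_filament_image(spec)
        result = measure_transition(analyze_image(image, window_px=1))
        assert abs(result.distance_px - truth.true_width_90_10_px) < 1.0

    def test_undetermined_direction_rejected(self):
        profile = profile_from_signal(gauss_signal(), direction=None)
        with pytest.raises(NoTransitionError):
            measure_transition(profile)

    def test_boundary_clipping_flagged(self):
        # the lo crossing falls in the profile's final sample interval
        r = np.r_[np.ones(30), 0.5, 0.0]
        result = measure_transition(profile_from_signal(r, mm_per_px=0.05))
        assert "clipped_at_boundary" in result.flags
        # a well-contained transition carries no flag
        contained = measure_transition(profile_from_signal(gauss_signal()))
        assert "clipped_at_boundary" not in contained.flags
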