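"""ESF and contrast metrics: sampling identities, change points, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr

from sstembatch import (
    LineProfile,
    VesicleAnnotation,
    compare_film_groups,
    detect_change_points,
    esf_slope,
    measure_vesicles,
    michelson_contrast,
    sample_line_profile,
    summarize_metric,
)
from sstembatch.exceptions import (
    AnnotationError,
    NoEdgeError,
    ParameterError,
    ProfileError,
)


def blurred_step_profile(delta_i=100.0, sigma=2.0, x0=20.0, length=40.0, step=0.25):
    """Analytic falling erf step: bright plateau -> dark plateau."""
    pos = np.arange(0.0, length + 1e-9, step)
    return LineProfile(positions=pos, intensities=delta_i * (1 - ndtr((pos - x0) / sigma)))


class TestSampleLineProfile:
    def test_constant_image(self):
        img = np.full((20, 20), 7.0)
        prof = sample_line_profile(img, VesicleAnnotation(2, 3, 12, 3))
        assert np.allclose(prof.intensities, 7.0)

    def test_axis_aligned_integer_steps_identity(self):
        img = np.arange(400, dtype=float).reshape(20, 20)
        prof = sample_line_profile(img, VesicleAnnotation(x_ext=2, y_ext=5, x_int=17, y_int=5), step=1.0)
        assert np.array_equal(prof.intensities, img[5, 2:18])

    def test_diagonal_midpoint_is_bilinear_mean(self):
        # two-valued image split by the anti-diagonal; the 45-degree line
        # crosses the boundary where bilinear weights average the two values
        img = np.zeros((21, 21))
        img[:, 11:] = 100.0
        prof = sample_line_profile(img, VesicleAnnotation(6, 6, 14, 14), step=0.5)
        crossing = prof.intensities[np.isclose(prof.positions, np.hypot(4.5, 4.5))]
        assert crossing == pytest.approx(50.0)

    def test_degenerate_annotation_rejected(self):
        with pytest.raises(AnnotationError):
            sample_line_profile(np.zeros((10, 10)), VesicleAnnotation(3, 3, 3, 3))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(AnnotationError):
            sample_line_profile(np.zeros((10, 10)), VesicleAnnotation(0, 0, 15, 0))

    def test_too_short_profile_rejected(self):
        with pytest.raises(ProfileError):
            sample_line_profile(np.zeros((10, 10)), VesicleAnnotation(0, 0, 2, 0), step=1.0)


class TestDetectChangePoints:
    def test_ideal_step_brackets_edge(self):
        pos = np.arange(0.0, 10.1, 0.25)
        inten = np.where(pos < 5.0, 100.0, 0.0)
        lo, hi = detect_change_points(LineProfile(pos, inten), smooth_sigma=1.0)
        # brackets the edge at 4.875 within +/- (smooth_sigma + 1.5) samples:
        # the 20% tail of the smoothing kernel sits at ~1.8 sigma and central
        # differencing widens the derivative support by one sample
        slack = (1.0 + 1.5) * 0.25
        assert 4.875 - slack - 1e-9 <= lo < hi <= 4.875 + slack + 1e-9
        assert lo < 4.875 < hi

    def test_linear_ramp_spans_whole_profile(self):
        pos = np.arange(0.0, 10.1, 0.5)
        lo, hi = detect_change_points(LineProfile(pos, 3.0 * pos))
        assert (lo, hi) == (pos[0], pos[-1])

    def test_flat_profile_has_no_edge(self):
        pos = np.arange(0.0, 10.1, 0.5)
        with pytest.raises(NoEdgeError):
            detect_change_points(LineProfile(pos, np.full_like(pos, 9.0)))

    def test_separation_grows_with_blur(self):
        widths = []
        for sigma in (1.0, 2.0, 4.0):
            lo, hi = detect_change_points(blurred_step_profile(sigma=sigma, length=60, x0=30))
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]


class TestEsfSlope:
    def test_recovers_exact_linear_segment(self):
        pos = np.arange(0.0, 20.1, 0.5)
        inten = np.piecewise(
            pos, [pos < 5, (pos >= 5) & (pos <= 15), pos > 15],
            [100.0, lambda x: 100.0 - 3.0 * (x - 5.0), 70.0],
        )
        res = esf_slope(LineProfile(pos, inten), (5.0, 15.0))
        assert res.slope == pytest.approx(-3.0)
        assert res.n_fit_points == 19

    def test_sharp_step_slope_bounded_by_sampling(self):
        # an idealized edge has infinite slope; the fitted estimate is
        # limited only by the sampling step (least-squares over the ~4
        # bracketed samples gives >= dI / (4 * step), doubling as the step
        # halves) and far exceeds any blurred-edge slope
        for step, bound in ((0.25, 100.0 / 1.0), (0.125, 100.0 / 0.5)):
            pos = np.arange(0.0, 10.0 + 1e-9, step)
            inten = np.where(pos < 5.0, 100.0, 0.0)
            prof = LineProfile(pos, inten)
            res = esf_slope(prof, detect_change_points(prof))
            assert abs(res.slope) >= bound

    def test_blurred_step_slope_near_analytic_maximum(self):
        prof = blurred_step_profile(delta_i=100.0, sigma=2.0)
        res = esf_slope(prof, detect_change_points(prof))
        analytic = 100.0 / (2.0 * np.sqrt(2 * np.pi))  # ~19.9
        assert abs(res.slope) == pytest.approx(analytic, rel=0.25)
        assert res.slope < 0  # bright exterior first -> falling

    def test_slope_magnitude_decreases_with_blur(self):
        mags = []
        for sigma in (1.0, 2.0, 4.0):
            prof = blurred_step_profile(sigma=sigma, length=60, x0=30)
            mags.append(abs(esf_slope(prof, detect_change_points(prof)).slope))
        assert mags[0] > mags[1] > mags[2]

    def test_insufficient_interior_points_rejected(self):
        prof = blurred_step_profile()
        with pytest.raises(ProfileError):
            esf_slope(prof, (10.0, 10.3))


class TestMichelsonContrast:
    @pytest.mark.parametrize(
        "i_int,i_ext,expected", [(80, 80, 0.0), (0, 50, 1.0), (60, 100, 0.25)]
    )
    def test_examples(self, i_int, i_ext, expected):
        assert michelson_contrast(i_int, i_ext) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ParameterError):
            michelson_contrast(0, 0)

    @given(
        i1=st.floats(0.0, 1e6),
        i2=st.floats(0.0, 1e6),
        k=st.floats(1e-6, 1e6),
    )
    def test_scale_invariant_and_bounded(self, i1, i2, k):
        if i1 + i2 == 0:
            return
        c = michelson_contrast(i1, i2)
        assert 0.0 <= c <= 1.0
        assert michelson_contrast(k * i1, k * i2) == pytest.approx(c, abs=1e-9)


class TestSummaries:
    def test_constant_values(self):
        s = summarize_metric([1, 1, 1])
        assert (s.mean, s.sd, s.n) == (1.0, 0.0, 3)

    def test_two_values(self):
        s = summarize_metric([0, 2])
        assert s.mean == 1.0
        assert s.sd == pytest.approx(np.sqrt(2))

    def test_sampling_distribution_of_the_mean(self):
        # 60 draws at the scale of reported per-film slope statistics
        rng = np.random.default_rng(2)
        vals = rng.normal(-2.98, 1.83, size=60)
        s = summarize_metric(vals)
        assert abs(s.mean - (-2.98)) <= 3 * 1.83 / np.sqrt(60)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            summarize_metric([])

    def test_compare_groups(self):
        report = compare_film_groups([1, 2, 3], [2, 3, 4])
        assert report["difference_of_means"] == pytest.approx(-1.0)
        assert report["group_a"].n == report["group_b"].n == 3
        same = compare_film_groups([5.0, 6.0], [5.0, 6.0])
        assert same["difference_of_means"] == 0.0


class TestOrientation:
    def test_reversing_annotation_negates_slope(self):
        img = np.tile(100.0 * (1 - ndtr((np.arange(40.0) - 20.0) / 2.0)), (12, 1))
        fwd = VesicleAnnotation(x_ext=4, y_ext=6, x_int=36, y_int=6)
        rev = VesicleAnnotation(x_ext=36, y_ext=6, x_int=4, y_int=6)
        res_f = measure_vesicles(img, [fwd]).iloc[0]
        res_r = measure_vesicles(img, [rev]).iloc[0]
        assert res_f.slope == pytest.approx(-res_r.slope, rel=1e-6)
        assert res_f.contrast == pytest.approx(res_r.contrast, rel=1e-6)
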