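"""Calibration fitting, SD correction, CV, growth marks, bimodality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhet import (CalibrationModel, GrowthPhaseMarks,
                      coefficient_of_variation, correct_sd,
                      expression_histogram3d, fit_calibration,
                      generate_calibration_series, mark_growth_phases,
                      max_promoter_activity, normalize_activity)
from microhet.heterogeneity import CalibrationError
from microhet.quantify import PopulationSnapshot
from microhet.simulate import calibration_points


class TestFitCalibration:
    def test_exact_line_recovered(self):
        means = np.array([50.0, 100.0, 200.0, 400.0])
        pts = list(zip(means, 0.1 * means + 2.0))
        m = fit_calibration(pts)
        assert m.slope == pytest.approx(0.1)
        assert m.intercept == pytest.approx(2.0)
        assert m.r_squared == pytest.approx(1.0)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_two_points_interpolate_exactly(self):
        m = fit_calibration([(10.0, 3.0), (20.0, 5.0)])
        assert m.slope == pytest.approx(0.2)
        assert m.intercept == pytest.approx(1.0)
        assert m.r_squared == 1.0 and m.n_points == 2

    def test_simulated_series_slope_recovery(self):
        slopes = []
        for seed in range(10):
            levels = generate_calibration_series((50, 100, 200, 400), 0.1, 5.0,
                                                 1000, rng_seed=seed)
            slopes.append(fit_calibration(calibration_points(levels)).slope)
        assert np.mean(slopes) == pytest.approx(0.1, rel=0.10)

    @pytest.mark.parametrize("pts", [[(10.0, 2.0)], [(10.0, 2.0), (10.0, 3.0)]])
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(CalibrationError):
            fit_calibration(pts)


class TestCorrectSD:
    MODEL = CalibrationModel(slope=0.1, intercept=5.0, r_squared=1.0,
                             n_points=4, residual_sd=0.0)

    def test_point_on_trend_line_corrects_to_zero(self):
        c = correct_sd(0.1 * 150 + 5.0, 150.0, self.MODEL)
        assert c.value == pytest.approx(0.0) and not c.clamped

    def test_arithmetic(self):
        c = correct_sd(30.0, 100.0, self.MODEL)
        assert c.value == pytest.approx(15.0)

    def test_below_trend_clamps_and_flags(self):
        c = correct_sd(10.0, 100.0, self.MODEL)  # trend = 15
        assert c.value == 0.0 and c.clamped

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(1, 1e3))
    def test_monotone_in_raw_sd(self, sd1, sd2, mean):
        lo, hi = sorted((sd1, sd2))
        assert (correct_sd(lo, mean, self.MODEL).value
                <= correct_sd(hi, mean, self.MODEL).value)

    def test_cv_values_and_domain(self):
        assert coefficient_of_variation(0.0, 10.0) == 0.0
        assert coefficient_of_variation(50.0, 200.0) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            coefficient_of_variation(1.0, 0.0)

    def test_cv_invariant_under_global_rescaling(self):
        # scaling samples AND controls by k leaves the CV unchanged
        means = np.array([50.0, 100.0, 200.0, 400.0])
        sds = 0.05 * means + 2.0
        sd_raw, mean = 30.0, 150.0
        def cv(k):
            m = fit_calibration(list(zip(k * means, k * sds)))
            c = correct_sd(k * sd_raw, k * mean, m)
            return coefficient_of_variation(c.value, k * mean)
        assert cv(3.7) == pytest.approx(cv(1.0), rel=1e-9)


class TestGrowthMarks:
    @staticmethod
    def _exp_then_flat(doubling=30.0, t_trans=300.0, t_end=480.0, dt=6.0):
        t = np.arange(0.0, t_end + dt, dt)
        f = 10.0 * 2.0 ** (np.minimum(t, t_trans) / doubling)
        return t, f

    def test_transition_within_one_frame_of_construction(self):
        t, f = self._exp_then_flat()
        marks = mark_growth_phases(t, f)
        assert abs(marks.t_transition - 300.0) <= 6.0
        assert marks.t_exponential < marks.t_transition
        # stationary marks sit 25% / 90% through the post-transition window
        span = t[-1] - marks.t_transition
        assert marks.t_early_stationary == pytest.approx(
            marks.t_transition + 0.25 * span)
        assert marks.t_late_stationary == pytest.approx(
            marks.t_transition + 0.9 * span)

    def test_user_marks_returned_verbatim(self):
        t, f = self._exp_then_flat()
        user = GrowthPhaseMarks(100.0, 290.0, 350.0, 450.0)
        assert mark_growth_phases(t, f, user_marks=user) is user

    def test_out_of_range_user_marks_raise(self):
        t, f = self._exp_then_flat()
        with pytest.raises(ValueError):
            mark_growth_phases(t, f, user_marks=GrowthPhaseMarks(
                100.0, 290.0, 350.0, 1000.0))
        with pytest.raises(ValueError):
            mark_growth_phases(t, f, user_marks=GrowthPhaseMarks(
                290.0, 100.0, 350.0, 450.0))  # not increasing

    def test_flat_curve_raises(self):
        t = np.arange(0, 120, 6.0)
        with pytest.raises(ValueError):
            mark_growth_phases(t, np.full_like(t, 50.0))

    def test_too_few_frames_raise(self):
        with pytest.raises(ValueError):
            mark_growth_phases([0, 6, 12], [1, 2, 4])


class TestMaxActivity:
    SNAPS = [PopulationSnapshot(t, 10, m, 1.0)
             for t, m in [(0, 5.0), (10, 20.0), (20, 80.0), (30, 75.0)]]

    def test_max_in_window(self):
        assert max_promoter_activity(self.SNAPS, (0, 30)) == 80.0

    def test_window_excludes(self):
        assert max_promoter_activity(self.SNAPS, (25, 30)) == 75.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            max_promoter_activity(self.SNAPS, (100, 200))

    def test_normalization(self):
        assert normalize_activity(80.0, 80.0) == 1.0
        assert normalize_activity(240.0, 80.0) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            normalize_activity(1.0, 0.0)


class TestHistogram3D:
    def test_identical_intensities_occupy_one_bin_per_time(self):
        times = np.repeat([0.0, 10.0, 20.0], 50)
        vals = np.full(150, 42.0)
        h = expression_histogram3d(times, vals, [0, 5, 15, 25],
                                   np.linspace(0, 100, 11))
        assert ((h.counts > 0).sum(axis=1) == 1).all()
        assert h.modes_per_time_bin() == [1, 1, 1]

    def test_row_sums_equal_pooled_counts(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 30, 500)
        vals = rng.normal(100, 10, 500)
        h = expression_histogram3d(times, vals, [0, 10, 20, 30],
                                   np.linspace(0, 200, 21))
        for k, (lo, hi) in enumerate(zip([0, 10, 20], [10, 20, 30])):
            inside = (times >= lo) & (times < hi) & (vals >= 0) & (vals <= 200)
            assert h.counts[k].sum() == inside.sum()

    def test_well_separated_mixture_is_bimodal(self):
        rng = np.random.default_rng(1)
        n = 400
        times = np.concatenate([np.full(n, 5.0), np.full(n, 5.0)])
        vals = np.concatenate([rng.normal(100, 20, n), rng.normal(1000, 20, n)])
        h = expression_histogram3d(times, vals, [0, 10],
                                   np.linspace(0, 1200, 41))
        assert h.modes_per_time_bin() == [2]
        assert h.bimodal_time_bins() == [True]

    def test_invalid_bins_raise(self):
        with pytest.raises(ValueError):
            expression_histogram3d([1.0], [1.0], [0], [0, 1])
        with pytest.raises(ValueError):
            expression_histogram3d([1.0], [1.0], [0, 1], [1, 0])
        with pytest.raises(ValueError):
            expression_histogram3d([], [], [0, 1], [0, 1])
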