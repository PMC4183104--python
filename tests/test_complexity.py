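import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from dyncomp.complexity import (
    ComplexityParams,
    complexity_matrix,
    complexity_series,
    distribution_measure,
    fluctuation_measure,
    mean_complexity_curve,
)
from dyncomp.core_data import RatingScale

from _oracles import oracle_distribution, oracle_fluctuation

SCALE = RatingScale(0, 6)

window7 = hst.lists(hst.integers(min_value=0, max_value=6), min_size=7, max_size=7).map(
    lambda v: np.array(v, dtype=float)
)


class TestWindowMeasures:
    @pytest.mark.parametrize(
        "window, expected_f",
        [
            ([3, 3, 3, 3, 3, 3, 3], 0.0),                       # constant
            ([0, 6, 0, 6, 0, 6, 0], 1.0),                       # maximal alternation
            ([0, 1, 2, 3, 4, 5, 6], 1 / 36),                    # monotone ramp
            ([0, 6, 0, 0, 0, 0, 0], (6 / 1 + 6 / 5) / 36),      # trailing plateau
        ],
    )
    def test_fluctuation_worked_examples(self, window, expected_f):
        assert fluctuation_measure(np.array(window, float), SCALE) == pytest.approx(
            expected_f, abs=1e-12
        )

    @pytest.mark.parametrize(
        "window, expected_d",
        [
            ([4, 4, 4, 4, 4, 4, 4], 0.0),           # zero scatter
            ([0, 1, 2, 3, 4, 5, 6], 1.0),           # perfect uniform coverage
            ([0, 0, 0, 6, 6, 6, 0], 1 - 14 / 56),   # clustered at the extremes
        ],
    )
    def test_distribution_worked_examples(self, window, expected_d):
        assert distribution_measure(np.array(window, float), SCALE) == pytest.approx(
            expected_d, abs=1e-12
        )

    def test_missing_value_gives_undefined(self):
        w = np.array([0, 1, np.nan, 3, 4, 5, 6])
        assert np.isnan(fluctuation_measure(w, SCALE))
        assert np.isnan(distribution_measure(w, SCALE))

    def test_out_of_scale_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fluctuation_measure(np.array([0, 1, 2, 3, 4, 5, 7.0]), SCALE)

    @settings(deadline=None, max_examples=300)
    @given(window7)
    def test_matches_bruteforce_oracles(self, w):
        assert fluctuation_measure(w, SCALE) == pytest.approx(
            oracle_fluctuation(w, 0, 6), abs=1e-12
        )
        assert distribution_measure(w, SCALE) == pytest.approx(
            oracle_distribution(w, 0, 6), abs=1e-12
        )

    @settings(deadline=None, max_examples=200)
    @given(window7)
    def test_bounds_and_constant_zero(self, w):
        f = fluctuation_measure(w, SCALE)
        d = distribution_measure(w, SCALE)
        assert 0.0 <= f <= 1.0 and 0.0 <= d <= 1.0
        if np.ptp(w) == 0:
            assert f == 0.0 and d == 0.0

    @settings(deadline=None, max_examples=200)
    @given(
        window7,
        hst.floats(min_value=0.1, max_value=50, allow_nan=False),
        hst.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    def test_affine_invariance(self, w, a, b):
        scale2 = RatingScale(a * 0 + b, a * 6 + b)
        f1 = fluctuation_measure(w, SCALE)
        f2 = fluctuation_measure(a * w + b, scale2)
        d1 = distribution_measure(w, SCALE)
        d2 = distribution_measure(a * w + b, scale2)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert d1 == pytest.approx(d2, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(window7)
    def test_time_reversal_invariance(self, w):
        assert fluctuation_measure(w, SCALE) == pytest.approx(
            fluctuation_measure(w[::-1], SCALE), abs=1e-12
        )
        assert distribution_measure(w, SCALE) == pytest.approx(
            distribution_measure(w[::-1], SCALE), abs=1e-12
        )


class TestComplexitySeries:
    def test_constant_series_all_zero(self, make_series):
        cs = complexity_series(make_series([3.0] * 20))
        assert len(cs) == 14
        assert np.all(cs.C_values == 0.0)

    def test_window_count(self, make_series, rng):
        n = 33
        vals = rng.integers(0, 7, n).astype(float)
        cs = complexity_series(make_series(vals))
        assert len(cs) == n - 7 + 1

    def test_c_equals_f_times_d(self, make_series, rng):
        vals = rng.integers(0, 7, 25).astype(float)
        cs = complexity_series(make_series(vals))
        np.testing.assert_allclose(cs.C_values, cs.F_values * cs.D_values, atol=1e-14)

    def test_burst_localization(self, make_series):
        vals = [3.0] * 13 + [0.0, 6.0, 0.0, 6.0, 0.0, 6.0, 0.0] + [3.0] * 10
        cs = complexity_series(make_series(vals))
        argmax_day = cs.days[np.nanargmax(cs.C_values)]
        # anchors whose 7-day windows overlap the alternation block [13, 19]
        assert 7 <= argmax_day <= 19

    def test_short_series_cites_validity_rule(self, make_series):
        with pytest.raises(ValueError, match="20"):
            complexity_series(make_series([1.0] * 19))

    def test_missing_contaminates_overlapping_windows_only(self, make_series):
        vals = (np.arange(24) % 7).astype(float)
        vals[10] = np.nan
        cs = complexity_series(make_series(vals))
        undefined = np.isnan(cs.C_values)
        expected = np.zeros(len(cs), bool)
        expected[max(0, 10 - 6): 11] = True
        np.testing.assert_array_equal(undefined, expected)


class TestComplexityMatrix:
    def test_shape_and_row_consistency(self, make_series, rng):
        va = rng.integers(0, 7, 20).astype(float)
        vb = rng.integers(0, 7, 20).astype(float)
        sa, sb = make_series(va, item_id="a"), make_series(vb, item_id="b")
        mat = complexity_matrix([sa, sb])
        assert mat.C.shape == (2, 14)
        np.testing.assert_array_equal(mat.row("a"), complexity_series(sa).C_values)
        np.testing.assert_array_equal(mat.row("b"), complexity_series(sb).C_values)

    def test_constant_item_row_zero(self, make_series, rng):
        sa = make_series([2.0] * 20, item_id="a")
        sb = make_series(rng.integers(0, 7, 20).astype(float), item_id="b")
        mat = complexity_matrix([sa, sb])
        assert np.all(mat.row("a") == 0.0)

    def test_unequal_axes_rejected(self, make_series, scale06):
        from dyncomp.core_data import RatingSeries

        sa = make_series([1.0] * 20, item_id="a")
        sb = RatingSeries("p001", "b", np.arange(1, 21), np.ones(20), scale06)
        with pytest.raises(ValueError, match="day axis"):
            complexity_matrix([sa, sb])


class TestMeanCurve:
    def test_two_row_mean(self, make_series):
        mat = complexity_matrix(
            [make_series([3.0] * 20, item_id="a"), make_series([3.0] * 20, item_id="b")]
        )
        mat.C = np.array([[0.0, 0.2] + [0.0] * 12, [0.4, 0.2] + [0.0] * 12])
        days, mean = mean_complexity_curve(mat)
        np.testing.assert_allclose(mean[:2], [0.2, 0.2])

    def test_single_row_identity(self, make_series, rng):
        mat = complexity_matrix([make_series(rng.integers(0, 7, 20).astype(float))])
        days, mean = mean_complexity_curve(mat)
        np.testing.assert_array_equal(mean, mat.C[0])

    def test_available_case_over_undefined(self):
        C = np.array([[0.1, np.nan], [0.3, 0.5]])
        days, mean = mean_complexity_curve(C, days=np.array([0, 1]))
        np.testing.assert_allclose(mean, [0.2, 0.5])
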