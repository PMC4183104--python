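import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from dyncomp.core_data import (
    EventMetadata,
    FactorMap,
    OutcomeSeries,
    RatingScale,
    RatingSeries,
    RatingsValidationError,
    factor_score_series,
    impute_short_gaps,
    load_factor_config,
    load_ratings,
    patient_mean_level,
    write_factor_config,
    write_ratings,
)


class TestTypes:
    def test_scale_requires_positive_range(self):
        with pytest.raises(ValueError):
            RatingScale(6, 6)

    def test_series_rejects_non_increasing_days(self, scale06):
        with pytest.raises(ValueError, match="strictly increasing"):
            RatingSeries("p", "i", np.array([0, 2, 2]), np.array([1.0, 2.0, 3.0]), scale06)

    def test_series_rejects_out_of_scale(self, scale06):
        with pytest.raises(ValueError, match="outside scale"):
            RatingSeries("p", "i", np.array([0, 1]), np.array([1.0, 7.0]), scale06)

    def test_bound_values_are_valid_not_clamped(self, make_series):
        s = make_series([0.0, 6.0, 3.0])
        assert s.values[0] == 0.0 and s.values[1] == 6.0

    def test_factor_map_rejects_double_assignment(self):
        with pytest.raises(ValueError, match="assigned to both"):
            FactorMap({"f1": ["a"], "f2": ["a"]}, motivation_item="a", symptom_factor="f1")

    def test_factor_map_requires_designated_ids(self):
        with pytest.raises(ValueError):
            FactorMap({"f1": ["a"]}, motivation_item="missing", symptom_factor="f1")

    def test_outcome_series_bounds(self):
        with pytest.raises(ValueError, match=r"\[0, 40\]"):
            OutcomeSeries("p", np.array([0, 3]), np.array([10.0, 41.0]))

    def test_event_ordering(self):
        with pytest.raises(ValueError):
            EventMetadata("p", treatment_start_day=0, treatment_end_day=50, erp_onset_day=60)


class TestRatingsIO:
    def test_three_row_csv_parses_to_one_series(self, tmp_path, scale06):
        f = tmp_path / "r.csv"
        f.write_text("patient_id,day,item_id,value\np1,1,a,2\np1,2,a,3\np1,3,a,\n")
        series = load_ratings(f, scale06)
        assert len(series) == 1
        s = series[0]
        assert len(s) == 3
        assert np.isnan(s.values[2])

    def test_out_of_scale_value_names_key(self, tmp_path, scale06):
        f = tmp_path / "r.csv"
        f.write_text("patient_id,day,item_id,value\np1,1,a,9\n")
        with pytest.raises(RatingsValidationError, match="patient='p1' item='a' day=1"):
            load_ratings(f, scale06)

    def test_duplicate_key_rejected(self, tmp_path, scale06):
        f = tmp_path / "r.csv"
        f.write_text("patient_id,day,item_id,value\np1,1,a,2\np1,1,a,3\n")
        with pytest.raises(RatingsValidationError, match="duplicate"):
            load_ratings(f, scale06)

    def test_malformed_day_names_row(self, tmp_path, scale06):
        f = tmp_path / "r.csv"
        f.write_text("patient_id,day,item_id,value\np1,1,a,2\np1,1.5,a,3\n")
        with pytest.raises(RatingsValidationError, match="row 3"):
            load_ratings(f, scale06)

    def test_roundtrip_preserves_values_and_missingness(self, tmp_path, make_series, scale06):
        s1 = make_series([2.0, np.nan, 4.0, 0.0], item_id="a")
        s2 = make_series([6.0, 5.0, np.nan, np.nan], item_id="b")
        f = tmp_path / "rt.csv"
        write_ratings([s1, s2], f)
        loaded = {s.item_id: s for s in load_ratings(f, scale06)}
        for orig in (s1, s2):
            got = loaded[orig.item_id]
            assert np.array_equal(got.days, orig.days)
            np.testing.assert_array_equal(got.values, orig.values)

    def test_factor_config_roundtrip(self, tmp_path, scale06):
        fmap = FactorMap(
            {"f1": ["a", "b"], "f2": ["c"]},
            motivation_item="a",
            symptom_factor="f2",
            boundary_factors=["f1"],
        )
        scales = {i: scale06 for i in ("a", "b", "c")}
        f = tmp_path / "factors.yaml"
        write_factor_config(fmap, scales, f)
        fmap2, scales2 = load_factor_config(f)
        assert fmap2.factors == fmap.factors
        assert fmap2.motivation_item == "a"
        assert scales2["c"].max_value == 6.0


class TestImputation:
    def test_midpoint_fill(self, make_series):
        out = impute_short_gaps(make_series([2.0, np.nan, 4.0]), max_gap=1)
        np.testing.assert_allclose(out.values, [2.0, 3.0, 4.0])

    def test_long_gap_untouched(self, make_series):
        vals = [2.0, np.nan, np.nan, np.nan, 4.0]
        out = impute_short_gaps(make_series(vals), max_gap=1)
        np.testing.assert_array_equal(out.values, vals)

    def test_leading_and_trailing_missing_left_alone(self, make_series):
        out = impute_short_gaps(make_series([np.nan, 3.0, np.nan]), max_gap=2)
        assert np.isnan(out.values[0]) and np.isnan(out.values[2])

    @settings(deadline=None, max_examples=60)
    @given(
        hst.lists(
            hst.one_of(hst.none(), hst.integers(min_value=0, max_value=6)),
            min_size=1,
            max_size=25,
        ),
        hst.integers(min_value=0, max_value=4),
    )
    def test_idempotent_and_preserves_observed(self, raw, max_gap):
        from dyncomp.core_data import RatingScale, RatingSeries

        vals = np.array([np.nan if v is None else float(v) for v in raw])
        s = RatingSeries("p", "i", np.arange(vals.size), vals, RatingScale(0, 6))
        once = impute_short_gaps(s, max_gap)
        twice = impute_short_gaps(once, max_gap)
        np.testing.assert_array_equal(once.values, twice.values)
        observed = ~np.isnan(vals)
        np.testing.assert_array_equal(once.values[observed], vals[observed])


class TestFactorScoring:
    @pytest.fixture
    def fmap(self):
        return FactorMap(
            {"f1": ["a", "b"], "f2": ["c"]}, motivation_item="c", symptom_factor="f1"
        )

    def test_per_day_mean(self, make_series, fmap):
        sa = make_series([4.0, 2.0], item_id="a")
        sb = make_series([6.0, 4.0], item_id="b")
        out = factor_score_series([sa, sb], "f1", fmap)
        np.testing.assert_allclose(out.values, [5.0, 3.0])

    def test_available_case_mean(self, make_series, fmap):
        sa = make_series([4.0, np.nan], item_id="a")
        sb = make_series([6.0, 4.0], item_id="b")
        out = factor_score_series([sa, sb], "f1", fmap)
        np.testing.assert_allclose(out.values, [5.0, 4.0])

    def test_single_item_factor_is_identity(self, make_series, fmap):
        sc = make_series([1.0, 2.0, np.nan], item_id="c")
        out = factor_score_series([sc], "f2", fmap)
        np.testing.assert_array_equal(out.values, sc.values)

    def test_identical_items_equal_any_single_item(self, make_series, fmap):
        vals = [3.0, 1.0, 5.0]
        out = factor_score_series(
            [make_series(vals, item_id="a"), make_series(vals, item_id="b")], "f1", fmap
        )
        np.testing.assert_allclose(out.values, vals)

    def test_heterogeneous_scales_error(self, make_series, fmap):
        sa = make_series([4.0], item_id="a")
        sb = make_series([4.0], item_id="b", scale=RatingScale(1, 7))
        with pytest.raises(ValueError, match="heterogeneous"):
            factor_score_series([sa, sb], "f1", fmap)


class TestMeanLevel:
    def test_constant_series(self, make_series):
        assert patient_mean_level(make_series([4.0] * 5)) == 4.0

    def test_day_range(self, make_series):
        s = make_series([3.0, 5.0, 1.0])
        assert patient_mean_level(s, (0, 1)) == 4.0

    def test_all_missing_range_errors(self, make_series):
        s = make_series([1.0, np.nan, np.nan])
        with pytest.raises(ValueError, match="no observed values"):
            patient_mean_level(s, (1, 2))
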