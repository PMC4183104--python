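import numpy as np
import pytest

from dyncomp.core_data import RatingScale, RatingSeries
from dyncomp.stats import (
    anova_2x2,
    correlate,
    hierarchical_regression,
    median_split,
    posthoc_t,
    relative_change,
    weekly_symptom_means,
)

from _oracles import (
    oracle_anova_2x2,
    oracle_hierarchical,
    oracle_pearson,
    oracle_posthoc_t,
)


class TestRelativeChange:
    def test_no_change(self):
        assert relative_change(20, 20) == 0.0

    def test_halving(self):
        assert relative_change(20, 10) == -50.0

    def test_cohort_mean_scores(self):
        # pre 21.8 -> post 14.7 on the 0-40 outcome scale
        assert relative_change(21.8, 14.7) == pytest.approx(-32.57, abs=0.005)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0, 5)


class TestWeeklyMeans:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return RatingSeries("p", "f", np.arange(values.size), values, RatingScale(0, 6))

    def test_constant(self):
        pre, post = weekly_symptom_means(self._series([4.5] * 21))
        assert (pre, post) == (4.5, 4.5)

    def test_first_vs_last_week(self):
        vals = [5.0] * 7 + [4.0] * 7 + [3.0] * 7
        pre, post = weekly_symptom_means(self._series(vals))
        assert (pre, post) == (5.0, 3.0)
        assert relative_change(pre, post) == -40.0

    def test_insufficient_coverage_names_week(self):
        vals = [5.0, np.nan, np.nan, np.nan, np.nan, np.nan, 5.0] + [3.0] * 14
        with pytest.raises(ValueError, match="first week"):
            weekly_symptom_means(self._series(vals))

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="14"):
            weekly_symptom_means(self._series([4.0] * 10))


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computable_four_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 0.0])
        res = correlate(x, y)
        r_o, p_o = oracle_pearson(x, y)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_matches_sum_formula_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = correlate(x, y)
            r_o, p_o = oracle_pearson(x, y)
            assert res.r == pytest.approx(r_o, abs=1e-8)
            assert res.p == pytest.approx(p_o, abs=1e-8)

    def test_listwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        assert correlate(x, y).n == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlate([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMedianSplit:
    def test_odd_n_tie_to_low(self):
        res = median_split([1, 2, 3, 4, 5])
        assert res.median == 3 and res.n_low == 3 and res.n_high == 2

    def test_23_distinct_values_split_12_11(self, rng):
        vals = rng.permutation(np.linspace(0.01, 0.5, 23))
        res = median_split(vals)
        assert (res.n_low, res.n_high) == (12, 11)

    def test_even_n_between_values(self):
        res = median_split([1, 1, 2, 2])
        assert res.median == 1.5 and res.n_low == 2 and res.n_high == 2

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="no split"):
            median_split([2.0, 2.0, 2.0, 2.0])


class TestAnova:
    def _random_design(self, rng, n):
        a = rng.random(n) > 0.5
        b = rng.random(n) > 0.5
        # guarantee non-empty cells
        a[:4] = [True, True, False, False]
        b[:4] = [True, False, True, False]
        y = rng.normal(size=n) + a * rng.normal() + b * rng.normal() + (a & b) * rng.normal()
        return y, a, b

    def test_matches_type3_oracle_on_random_unbalanced_data(self, rng):
        for _ in range(30):
            n = int(rng.integers(12, 30))
            y, a, b = self._random_design(rng, n)
            got = anova_2x2(y, np.where(a, "high", "low"), np.where(b, "high", "low"))
            exp = oracle_anova_2x2(y, a, b)
            for key in ("a", "b", "a:b"):
                assert got[key].F == pytest.approx(exp[key]["F"], abs=1e-8)
                assert got[key].p == pytest.approx(exp[key]["p"], abs=1e-8)
                assert got[key].partial_eta_sq == pytest.approx(
                    exp[key]["partial_eta_sq"], abs=1e-8
                )
                assert 0.0 <= got[key].partial_eta_sq <= 1.0

    def test_additive_balanced_no_interaction(self):
        # cell means exactly additive, zero noise
        y = np.array([1.0, 1.0, 3.0, 3.0, 2.0, 2.0, 4.0, 4.0])
        a = ["low"] * 4 + ["high"] * 4
        b = (["low", "low", "high", "high"]) * 2
        res = anova_2x2(y, a, b)
        assert res["a:b"].F == pytest.approx(0.0, abs=1e-10)

    def test_pure_crossover_interaction(self):
        y = np.array([1.0, 1.0, -1.0, -1.0, -1.0, -1.0, 1.0, 1.0])
        a = ["low"] * 4 + ["high"] * 4
        b = (["low", "low", "high", "high"]) * 2
        res = anova_2x2(y, a, b)
        assert res["a"].F == pytest.approx(0.0, abs=1e-10)
        assert res["b"].F == pytest.approx(0.0, abs=1e-10)
        assert res["a:b"].F > 10

    def test_empty_cell_rejected(self):
        y = np.arange(6.0)
        a = ["low", "low", "low", "high", "high", "high"]
        b = ["low", "high", "low", "low", "low", "low"]
        with pytest.raises(ValueError, match="empty cell"):
            anova_2x2(y, a, b)


class TestPosthoc:
    def test_identical_groups(self):
        res = posthoc_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohen_d == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            posthoc_t([0.0, 0.0], [1.0, 1.0])

    def test_textbook_example(self):
        res = posthoc_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        t_o, p_o, d_o = oracle_posthoc_t([1, 2, 3], [3, 4, 5])
        assert res.t == pytest.approx(t_o, abs=1e-12)
        assert res.cohen_d == pytest.approx(d_o, abs=1e-12)
        assert res.cohen_d == pytest.approx(-2.0)
        assert res.df == 4

    def test_matches_oracle_on_random_groups(self, rng):
        for _ in range(40):
            g1 = rng.normal(size=int(rng.integers(3, 15)))
            g2 = rng.normal(0.5, 1.2, size=int(rng.integers(3, 15)))
            res = posthoc_t(g1, g2)
            t_o, p_o, d_o = oracle_posthoc_t(g1, g2)
            assert res.t == pytest.approx(t_o, abs=1e-8)
            assert res.p == pytest.approx(p_o, abs=1e-8)
            assert res.cohen_d == pytest.approx(d_o, abs=1e-8)


class TestHierarchicalRegression:
    def test_single_block_r2_equals_r_squared(self, rng):
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        blocks = hierarchical_regression(y, [("x", {"x": x})])
        r = correlate(x, y).r
        assert blocks[0].r_squared == pytest.approx(r**2, abs=1e-10)

    def test_orthogonal_blocks_sum_to_full_r2(self, rng):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
        blocks = hierarchical_regression(y, [("b1", {"x1": x1}), ("b2", {"x2": x2})])
        assert blocks[0].r_squared_change + blocks[1].r_squared_change == pytest.approx(
            blocks[1].r_squared, abs=1e-10
        )

    def test_noise_block_nonnegative_gain(self, rng):
        for _ in range(20):
            y = rng.normal(size=15)
            x = rng.normal(size=15)
            z = rng.normal(size=15)
            blocks = hierarchical_regression(y, [("x", {"x": x}), ("noise", {"z": z})])
            assert blocks[1].r_squared_change >= -1e-12

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(12, 30))
            x1, x2, x3 = rng.normal(size=(3, n))
            y = 0.4 * x1 - 0.5 * x2 + rng.normal(size=n)
            got = hierarchical_regression(
                y, [("m", {"x1": x1}), ("w", {"x2": x2}), ("c", {"x3": x3})]
            )
            exp = oracle_hierarchical(y, [[x1], [x2], [x3]])
            for g, e in zip(got, exp):
                assert g.r_squared == pytest.approx(e["r_squared"], abs=1e-8)
                assert g.r_squared_change == pytest.approx(e["r_squared_change"], abs=1e-8)
                assert g.f_change == pytest.approx(e["f_change"], abs=1e-6)
                assert g.p_change == pytest.approx(e["p_change"], abs=1e-8)
                np.testing.assert_allclose(
                    [g.beta[k] for k in g.predictors], e["beta"], atol=1e-8
                )

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            hierarchical_regression(x + 1, [("b", {"x1": x, "x2": 2 * x})])
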