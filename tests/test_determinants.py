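"""Determinant association: correlations, screening, stepwise, rank composite."""

import numpy as np
import pandas as pd
import pytest

from tractrisk import (
    CollinearityError,
    ConfigError,
    StatisticError,
    backward_stepwise,
    multivariate_fit,
    pearson_correlation,
    rank_composite,
    univariate_screen,
)

from conftest import ols_oracle


def summary_from(diff_frac, ids=None):
    ids = ids or [f"T{i}" for i in range(len(diff_frac))]
    return pd.DataFrame({
        "tract_id": ids,
        "difference_per_100k": np.asarray(diff_frac) * 1e5,
        "population": 1000,
    })


def det_table(ids=None, **cols):
    n = len(next(iter(cols.values())))
    ids = ids or [f"T{i}" for i in range(n)]
    return pd.DataFrame({"tract_id": ids, **cols})


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestUnivariateScreen:
    def test_bonferroni_threshold_twenty_tests(self):
        rng = np.random.default_rng(1)
        n = 40
        cols = {f"d{i:02d}": rng.normal(size=n) for i in range(20)}
        screen = univariate_screen(summary_from(rng.normal(size=n) * 1e-3),
                                   det_table(**cols), alpha=0.05)
        assert screen.m == 20
        assert screen.bonferroni_threshold == pytest.approx(0.0025)

    def test_single_test_threshold_is_alpha(self):
        rng = np.random.default_rng(2)
        screen = univariate_screen(summary_from(rng.normal(size=10) * 1e-3),
                                   det_table(x=rng.normal(size=10)))
        assert screen.bonferroni_threshold == pytest.approx(0.05)

    def test_hand_computed_slope_and_intercept(self):
        # x=(0,1,2), y=(1,2,4): slope 1.5, intercept 5/6
        screen = univariate_screen(summary_from([1, 2, 4]),
                                   det_table(x=[0.0, 1.0, 2.0]))
        res = screen.results["x"]
        assert res.term("x").slope == pytest.approx(1.5)
        assert res.intercept.slope == pytest.approx(5 / 6)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.002 * x + rng.normal(0, 0.003, 30)
        screen = univariate_screen(summary_from(y), det_table(x=x))
        res = screen.results["x"].term("x")
        beta, lo, hi, p = ols_oracle(y, x.reshape(-1, 1))
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.ci95 == pytest.approx((lo[1], hi[1]), abs=1e-10)
        assert res.p_value == pytest.approx(p[1], abs=1e-10)

    def test_all_missing_determinant_skipped(self, caplog):
        import logging
        rng = np.random.default_rng(4)
        dets = det_table(x=rng.normal(size=10), empty=[np.nan] * 10)
        with caplog.at_level(logging.WARNING, logger="tractrisk.determinants"):
            screen = univariate_screen(summary_from(rng.normal(size=10) * 1e-3), dets)
        assert set(screen.results) == {"x"}
        assert screen.m == 1

    def test_significant_flag_monotone_in_m(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=n)
        y = 0.004 * x + rng.normal(0, 0.004, n)
        small = univariate_screen(summary_from(y), det_table(x=x))
        cols = {f"noise{i}": rng.normal(size=n) for i in range(14)}
        large = univariate_screen(summary_from(y), det_table(x=x, **cols))
        assert large.table.loc["x", "p_value"] == small.table.loc["x", "p_value"]
        assert set(large.significant) <= set(small.significant) | set(cols)


class TestMultivariateFit:
    def test_single_term_matches_univariate(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        y = 0.003 * x + rng.normal(0, 0.002, 25)
        summary, dets = summary_from(y), det_table(x=x)
        uni = univariate_screen(summary, dets).results["x"]
        multi = multivariate_fit(summary, dets, ["x"])
        assert multi.term("x").slope == pytest.approx(uni.term("x").slope, abs=1e-12)
        assert multi.term("x").p_value == pytest.approx(uni.term("x").p_value, abs=1e-12)

    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.normal(size=12), rng.normal(size=12)
        y = 0.5 * x1 - 0.2 * x2 + 0.1
        fit = multivariate_fit(summary_from(y), det_table(x1=x1, x2=x2), ["x1", "x2"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.normal(size=10), rng.normal(size=10)
        y = 0.01 * x1 + rng.normal(0, 0.02, 10)
        fit = multivariate_fit(summary_from(y), det_table(x1=x1, x2=x2), ["x1", "x2"])
        n, k = 10, 2
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - k - 1)
        assert fit.adjusted_r2 == pytest.approx(expected, abs=1e-12)

    def test_matches_normal_equations_oracle_two_terms(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        y = 0.004 * X[:, 0] - 0.002 * X[:, 1] + rng.normal(0, 0.003, 40)
        fit = multivariate_fit(summary_from(y), det_table(a=X[:, 0], b=X[:, 1]),
                               ["a", "b"])
        beta, lo, hi, p = ols_oracle(y, X)
        assert fit.term("a").slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.term("b").slope == pytest.approx(beta[2], abs=1e-10)
        assert fit.term("b").ci95 == pytest.approx((lo[2], hi[2]), abs=1e-10)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        with pytest.raises(CollinearityError) as exc:
            multivariate_fit(summary_from(rng.normal(size=15) * 1e-3),
                             det_table(a=x, twice_a=2 * x), ["a", "twice_a"])
        assert "twice_a" in exc.value.terms

    def test_unknown_term_rejected(self):
        with pytest.raises(ConfigError):
            multivariate_fit(summary_from([1, 2, 3, 4, 5]),
                             det_table(x=[1.0, 2, 3, 4, 5]), ["ghost"])


class TestBackwardStepwise:
    def test_all_significant_nothing_removed(self):
        rng = np.random.default_rng(11)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        y = 0.01 * x1 + 0.01 * x2 + rng.normal(0, 0.002, 50)
        retained, trace = backward_stepwise(
            summary_from(y), det_table(x1=x1, x2=x2), ["x1", "x2"])
        assert retained == ["x1", "x2"]
        assert len(trace) == 1 and trace[0]["dropped"] is None

    def test_noise_term_eliminated(self):
        rng = np.random.default_rng(12)
        x, noise = rng.normal(size=60), rng.normal(size=60)
        y = 0.01 * x + rng.normal(0, 0.002, 60)
        retained, trace = backward_stepwise(
            summary_from(y), det_table(x=x, noise=noise), ["x", "noise"])
        assert retained == ["x"]
        assert trace[0]["dropped"] == "noise"

    def test_stops_at_single_term(self):
        rng = np.random.default_rng(13)
        n1, n2 = rng.normal(size=20), rng.normal(size=20)
        y = rng.normal(0, 0.01, 20)  # pure noise response
        retained, _ = backward_stepwise(summary_from(y), det_table(n1=n1, n2=n2),
                                        ["n1", "n2"])
        assert len(retained) == 1

    def test_trace_records_adjusted_r2_per_step(self):
        rng = np.random.default_rng(14)
        x, noise = rng.normal(size=40), rng.normal(size=40)
        y = 0.01 * x + rng.normal(0, 0.003, 40)
        _, trace = backward_stepwise(summary_from(y), det_table(x=x, noise=noise),
                                     ["x", "noise"])
        assert all("adjusted_r2" in step for step in trace)
        assert len(trace) >= 2


class TestRankComposite:
    def test_hand_mean_ranks(self):
        dets = det_table(ids=["A", "B", "C"], d1=[1.0, 2.0, 3.0], d2=[20.0, 10.0, 30.0])
        summary = summary_from([0.001, 0.0, -0.001], ids=["A", "B", "C"])
        rc = rank_composite(summary, dets, ["d1", "d2"],
                            {"d1": "favorable_low", "d2": "favorable_low"})
        assert rc.mean_rank.tolist() == [1.5, 1.5, 3.0]

    def test_single_determinant_equals_own_rank(self):
        dets = det_table(ids=["A", "B", "C"], d=[5.0, 1.0, 3.0])
        summary = summary_from([0.0, 0.001, -0.001], ids=["A", "B", "C"])
        rc = rank_composite(summary, dets, ["d"], {"d": "favorable_high"})
        # favorable_high: largest value ranks 1
        assert rc.mean_rank.tolist() == [1.0, 3.0, 2.0]

    def test_ties_get_average_rank(self):
        dets = det_table(ids=["A", "B", "C"], d=[2.0, 2.0, 5.0])
        summary = summary_from([0.001, -0.001, 0.0], ids=["A", "B", "C"])
        rc = rank_composite(summary, dets, ["d"], {"d": "favorable_low"})
        assert rc.mean_rank.tolist() == [1.5, 1.5, 3.0]

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(15)
        vals = rng.uniform(1, 10, 20)
        diff = rng.normal(0, 0.002, 20)
        base = det_table(d=vals)
        transformed = det_table(d=np.exp(vals))
        o = {"d": "favorable_low"}
        rc1 = rank_composite(summary_from(diff), base, ["d"], o)
        rc2 = rank_composite(summary_from(diff), transformed, ["d"], o)
        assert rc1.mean_rank.tolist() == rc2.mean_rank.tolist()
        assert rc1.regression.term("mean_rank").slope == pytest.approx(
            rc2.regression.term("mean_rank").slope)

    def test_unoriented_determinant_rejected(self):
        dets = det_table(d=[1.0, 2.0, 3.0])
        with pytest.raises(ConfigError):
            rank_composite(summary_from([0.0, 0.001, 0.002]), dets, ["d"], {})
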