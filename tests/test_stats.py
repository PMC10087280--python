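"""Correlation/regression statistics against direct-summation oracles, the
coincidence test's algebraic identities, and the data filters."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from brgdgt.stats import (
    coincidence_test,
    filter_saturated,
    multiple_ols,
    ols_fit,
    pearson_test,
    remove_rmse_outliers,
    subset_analysis,
)


def oracle_pearson(x, y):
    """Textbook product-moment formula with an explicit t-test, written
    independently of the implementation under test."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r_ = min(max(r, -1.0), 1.0)
    t = r_ * math.sqrt((n - 2) / (1 - r_**2)) if abs(r_) < 1 else math.inf
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def oracle_ols(x, y):
    """Closed-form simple OLS with classical standard errors."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((b - intercept - slope * a) ** 2 for a, b in zip(x, y))
    s2 = sse / (n - 2)
    slope_se = math.sqrt(s2 / sxx)
    intercept_se = math.sqrt(s2 * (1 / n + mx**2 / sxx))
    syy = sum((b - my) ** 2 for b in y)
    r2 = 1 - sse / syy
    return slope, intercept, slope_se, intercept_se, r2, math.sqrt(s2)


class TestPearson:
    def test_collinear(self):
        res = pearson_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_hand_value(self):
        res = pearson_test([1, 2, 3], [2, 4, 5])
        assert round(res.r, 4) == 0.9820

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1, 2], [3, 4])


class TestOls:
    def test_exact_line(self):
        res = ols_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant x"):
            ols_fit([2, 2, 2, 2], [1, 2, 3, 4])

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            if np.ptp(y) == 0:
                continue
            assert np.sign(pearson_test(x, y).r) == np.sign(ols_fit(x, y).slope)


def test_oracle_agreement_random_instances(rng):
    """pearson_test and ols_fit match direct-summation formulas to 1e-10."""
    for _ in range(1000):
        n = int(rng.integers(3, 12))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:  # pragma: no cover
            continue
        r, p = oracle_pearson(list(x), list(y))
        got = pearson_test(x, y)
        assert got.r == pytest.approx(r, abs=1e-10)
        assert got.p == pytest.approx(p, abs=1e-10)
        if n >= 3:
            slope, intercept, slope_se, intercept_se, r2, rmse = oracle_ols(list(x), list(y))
            fit = ols_fit(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.slope_se == pytest.approx(slope_se, abs=1e-10)
            assert fit.intercept_se == pytest.approx(intercept_se, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.rmse == pytest.approx(rmse, abs=1e-10)


class TestMultipleOls:
    def test_exact_coefficients(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = 3 + 2 * x1 - x2
        coefs = multiple_ols(y, {"x1": x1, "x2": x2})
        assert coefs.loc["intercept", "estimate"] == pytest.approx(3.0, abs=1e-10)
        assert coefs.loc["x1", "estimate"] == pytest.approx(2.0, abs=1e-10)
        assert coefs.loc["x2", "estimate"] == pytest.approx(-1.0, abs=1e-10)

    def test_pure_noise_predictor_not_significant(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        y = 1.0 + 0.8 * x1 + rng.normal(scale=0.3, size=60)
        coefs = multiple_ols(y, {"x1": x1, "x2": x2})
        assert coefs.loc["x1", "p"] < 0.05
        assert coefs.loc["x2", "p"] > 0.05

    def test_rank_deficiency_named(self):
        x1 = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            multiple_ols(x1, {"a": x1, "b": 2 * x1})


class TestCoincidence:
    def test_duplicated_dataset_is_coincident(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 2 * x + 1 + rng.normal(0, 0.5, 30)
        res = coincidence_test(x, y, x, y)
        assert res.delta_slope == pytest.approx(0.0, abs=1e-10)
        assert res.delta_intercept == pytest.approx(0.0, abs=1e-10)
        assert "coincident" in res.classification

    def test_reduces_to_env_fit(self, rng):
        """Base slope/intercept of the pooled model equal the separate
        environmental-group OLS (algebraic identity of the interaction model)."""
        ex = rng.uniform(0, 20, 40)
        ey = 0.03 * ex + 0.1 + rng.normal(0, 0.05, 40)
        cx = rng.uniform(10, 30, 20)
        cy = 0.05 * cx - 0.2 + rng.normal(0, 0.05, 20)
        res = coincidence_test(ex, ey, cx, cy)
        env = ols_fit(ex, ey)
        assert res.slope == pytest.approx(env.slope, abs=1e-10)
        assert res.intercept == pytest.approx(env.intercept, abs=1e-10)
        # and the deltas equal the separate-fit differences
        cul = ols_fit(cx, cy)
        assert res.delta_slope == pytest.approx(cul.slope - env.slope, abs=1e-10)
        assert res.delta_intercept == pytest.approx(cul.intercept - env.intercept, abs=1e-10)

    def test_parallel_offset_detected(self):
        rng = np.random.default_rng(99)
        x1 = rng.uniform(0, 10, 50)
        x2 = rng.uniform(0, 10, 50)
        y1 = 2 * x1 + 1 + rng.normal(0, 0.2, 50)
        y2 = 2 * x2 + 3 + rng.normal(0, 0.2, 50)
        res = coincidence_test(x1, y1, x2, y2)
        assert res.p_delta_slope > 0.05
        assert res.p_delta_intercept < 0.05
        assert res.classification == frozenset({"parallel"})

    def test_classification_invariants(self, rng):
        for _ in range(30):
            ex = rng.uniform(0, 10, 12)
            ey = rng.normal(size=12) + 0.3 * ex
            cx = rng.uniform(0, 10, 12)
            cy = rng.normal(size=12) + 0.3 * cx
            res = coincidence_test(ex, ey, cx, cy)
            labels = res.classification
            assert ("coincident" in labels) == (
                "concurrent" in labels and "parallel" in labels
            )
            assert ("distinct" in labels) == (
                "concurrent" not in labels and "parallel" not in labels
            )

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant x"):
            coincidence_test([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestOutlierRemoval:
    @staticmethod
    def _line_plus_center_offset(n=12, d=1.0):
        # symmetric x, exact line, one extra point at the mean offset by d:
        # the offset point's residual/RMSE ratio is sqrt((n-1)(n-2)/n)
        x = np.concatenate([np.linspace(-5, 5, n - 1), [0.0]])
        y = 2 * x + 1
        y[-1] += d
        return x, y

    def test_gross_outlier_removed_and_clean_line_kept(self):
        x, y = self._line_plus_center_offset(n=12)
        kx, ky, removed = remove_rmse_outliers(x, y, k=3.0)
        assert list(removed) == [11]
        assert len(kx) == 11
        # a perfect line loses nothing
        _, _, removed2 = remove_rmse_outliers(kx, ky, k=3.0)
        assert removed2.size == 0

    def test_boundary_is_strict(self):
        """A point at exactly k*RMSE is retained (strict inequality)."""
        x, y = self._line_plus_center_offset(n=12)
        fit = ols_fit(x, y)
        ratio = abs(y[-1] - fit.intercept - fit.slope * x[-1]) / fit.rmse
        _, _, removed = remove_rmse_outliers(x, y, k=ratio)
        assert removed.size == 0
        _, _, removed = remove_rmse_outliers(x, y, k=ratio * 0.999)
        assert list(removed) == [11]

    def test_single_pass_no_iteration(self):
        # two moderate outliers: both judged against the *initial* fit
        x = np.concatenate([np.linspace(0, 10, 20), [5.0, 5.1]])
        y = np.concatenate([np.linspace(0, 10, 20) * 2 + 1, [30.0, -20.0]])
        _, _, removed = remove_rmse_outliers(x, y, k=1.0)
        fit = ols_fit(x, y)
        resid = y - fit.intercept - fit.slope * x
        expected = set(np.flatnonzero(np.abs(resid) > fit.rmse))
        assert set(removed) == expected


class TestFilters:
    def test_filter_saturated(self):
        vals = np.array([1.0, 0.999, 1.0 - 5e-10, 0.5, np.nan])
        keep = filter_saturated(vals, 1.0)
        assert list(keep) == [False, True, False, True, True]

    def test_empty_input(self):
        assert filter_saturated(np.array([])).size == 0


class TestSubsetAnalysis:
    def test_small_subset_not_evaluable(self, rng):
        x = rng.uniform(0, 1, 10)
        y = x + rng.normal(0, 0.01, 10)
        res = subset_analysis(x, y, {"tiny": np.arange(10) < 2})
        assert res["tiny"]["evaluable"] is False

    def test_all_data_matches_pearson(self, rng):
        x = rng.uniform(0, 1, 20)
        y = 2 * x + rng.normal(0, 0.2, 20)
        res = subset_analysis(x, y, {"all": np.ones(20, dtype=bool)})
        direct = pearson_test(x, y)
        assert res["all"]["correlation"].r == pytest.approx(direct.r)

    def test_regression_only_when_significant(self, rng):
        x = rng.uniform(0, 1, 30)
        noise = rng.normal(size=30)
        strong = 3 * x + 0.05 * noise
        res = subset_analysis(x, np.column_stack([strong]).ravel(),
                              {"all": np.ones(30, dtype=bool)})
        assert res["all"]["regression"] is not None
        weak = rng.normal(size=30)  # independent of x
        res2 = subset_analysis(x, weak, {"all": np.ones(30, dtype=bool)})
        if res2["all"]["correlation"].p >= 0.05:
            assert res2["all"]["regression"] is None
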