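import itertools
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from fishsde import iqr_outlier_filter, linear_regression, two_way_anova


def brute_force_balanced_anova(values, a_labels, b_labels):
    """Classical sums-of-squares decomposition for a balanced design."""
    values = np.asarray(values, float)
    a_labels, b_labels = np.asarray(a_labels), np.asarray(b_labels)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    levels_a = sorted(set(a_labels.tolist()))
    levels_b = sorted(set(b_labels.tolist()))
    ss_a = sum(
        (a_labels == la).sum() * (values[a_labels == la].mean() - grand) ** 2
        for la in levels_a
    )
    ss_b = sum(
        (b_labels == lb).sum() * (values[b_labels == lb].mean() - grand) ** 2
        for lb in levels_b
    )
    ss_cells = sum(
        ((a_labels == la) & (b_labels == lb)).sum()
        * (values[(a_labels == la) & (b_labels == lb)].mean() - grand) ** 2
        for la, lb in itertools.product(levels_a, levels_b)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = ss_total - ss_cells
    return ss_a, ss_b, ss_ab, ss_res, ss_total


class TestTwoWayAnova:
    def balanced_data(self, rng=None):
        a = np.repeat(["x", "y"], 8)
        b = np.tile(np.repeat(["u", "v"], 4), 2)
        if rng is None:
            vals = np.array([1.0, 1.1, 0.9, 1.0, 2.0, 2.1, 1.9, 2.0,
                             3.0, 3.2, 2.8, 3.0, 3.9, 4.1, 4.0, 4.0])
        else:
            vals = rng.normal(size=16)
        return vals, a, b

    def test_matches_brute_force_decomposition(self):
        vals, a, b = self.balanced_data()
        res = two_way_anova(vals, a, b)
        ss_a, ss_b, ss_ab, ss_res, ss_total = brute_force_balanced_anova(
            vals, a, b
        )
        assert res.effects["A"].ss == pytest.approx(ss_a, abs=1e-10)
        assert res.effects["B"].ss == pytest.approx(ss_b, abs=1e-10)
        assert res.effects["A:B"].ss == pytest.approx(ss_ab, abs=1e-10)
        assert res.ss_residual == pytest.approx(ss_res, abs=1e-10)
        assert res.ss_total == pytest.approx(ss_total, abs=1e-10)

    def test_matches_statsmodels_type2_when_unbalanced(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        n = [5, 4, 6, 5]  # mildly unbalanced
        rows = []
        means = {("x", "u"): 0.0, ("x", "v"): 1.5, ("y", "u"): 0.5,
                 ("y", "v"): 2.5}
        for (la, lb), k in zip(
            itertools.product(["x", "y"], ["u", "v"]), n
        ):
            for v in rng.normal(loc=means[(la, lb)], size=k):
                rows.append((v, la, lb))
        df = pd.DataFrame(rows, columns=["val", "A", "B"])
        res = two_way_anova(df["val"], df["A"], df["B"])
        ref = sm.stats.anova_lm(
            ols("val ~ C(A) * C(B)", data=df).fit(), typ=2
        )
        assert res.effects["A"].ss == pytest.approx(ref.loc["C(A)", "sum_sq"])
        assert res.effects["B"].ss == pytest.approx(ref.loc["C(B)", "sum_sq"])
        assert res.effects["A:B"].ss == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"]
        )
        assert res.effects["A"].p == pytest.approx(ref.loc["C(A)", "PR(>F)"])

    def test_eta_squared_sums_to_one_with_residual(self):
        vals, a, b = self.balanced_data()
        res = two_way_anova(vals, a, b)
        total_eta = sum(e.eta_squared for e in res.effects.values())
        assert total_eta + res.ss_residual / res.ss_total == pytest.approx(
            1.0, abs=1e-10
        )

    def test_zero_within_cell_variance(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        a = np.repeat(["x", "y"], 4)
        b = np.tile(np.repeat(["u", "v"], 2), 2)
        res = two_way_anova(vals, a, b)
        assert res.ss_residual == pytest.approx(0.0, abs=1e-12)
        assert res.effects["A"].p == pytest.approx(0.0, abs=1e-12)

    def test_empty_cell_named_in_error(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        a = ["x", "x", "y", "y"]
        b = ["u", "v", "u", "u"]
        with pytest.raises(ValueError, match="'y'.*'v'"):
            two_way_anova(vals, a, b)

    def test_null_p_values_uniform(self, rng):
        ps = []
        a = np.repeat(["x", "y"], 10)
        b = np.tile(np.repeat(["u", "v"], 5), 2)
        for _ in range(300):
            vals = rng.normal(size=20)
            ps.append(two_way_anova(vals, a, b).effects["A"].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.005


class TestIQRFilter:
    def test_textbook_outlier(self):
        kept, removed = iqr_outlier_filter([1.0, 2.0, 3.0, 4.0, 100.0])
        np.testing.assert_allclose(kept, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(removed, [100.0])

    def test_all_equal_untouched(self):
        kept, removed = iqr_outlier_filter(np.full(6, 3.0))
        assert len(kept) == 6 and len(removed) == 0

    def test_idempotent(self, rng):
        v = rng.normal(size=50)
        v[0] = 40.0
        once, _ = iqr_outlier_filter(v)
        twice, removed2 = iqr_outlier_filter(once)
        np.testing.assert_allclose(twice, once)
        assert len(removed2) == 0

    def test_small_sample_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = iqr_outlier_filter([1.0, 2.0, 3.0])
        assert len(kept) == 3 and len(removed) == 0


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=200)
        y = 1.5 * x - 0.3 + rng.normal(0, 0.5, 200)
        res = linear_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_null_slope_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = linear_regression(x, y)
        assert abs(res.slope) < 0.15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            linear_regression([1.0, 2.0], [1.0, 2.0])
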