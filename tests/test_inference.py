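"""Regression reports, incremental adjusted R² and summary-statistic tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wlscore as w
from wlscore.errors import DegenerateDataError, FitError, ValidationError


class TestOlsFit:
    def test_perfect_linear_fit(self):
        x = np.arange(20.0)
        rep = w.ols_fit(3.0 + 2.0 * x, x)
        assert rep.table["beta"].iloc[0] == pytest.approx(2.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.adj_r2 == pytest.approx(1.0)

    def test_null_predictor_adj_r2_near_zero(self):
        rng = np.random.default_rng(0)
        rep = w.ols_fit(rng.normal(size=500), rng.normal(size=500))
        assert abs(rep.adj_r2) < 0.02
        assert rep.table["ci_low"].iloc[0] < rep.table["beta"].iloc[0] < rep.table["ci_high"].iloc[0]

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = X @ [0.5, -1.0, 0.2] + rng.normal(size=80)
        rep = w.ols_fit(y, pd.DataFrame(X, columns=["a", "b", "c"]))
        design = np.column_stack([np.ones(80), X])
        beta_hat = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(rep.table["beta"], beta_hat[1:], rtol=1e-10)
        resid = y - design @ beta_hat
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert rep.r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        assert rep.adj_r2 == pytest.approx(
            1 - (1 - rep.r2) * (80 - 1) / (80 - 3 - 1), rel=1e-12
        )

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(FitError, match="collinear") as exc:
            w.ols_fit(rng.normal(size=50), X)
        assert "a" in str(exc.value) and "b" in str(exc.value)

    def test_too_few_rows_rejected(self):
        with pytest.raises(FitError, match="too small"):
            w.ols_fit([1.0, 2.0], [[1.0, 2.0], [3.0, 4.0]])


class TestIncrementalR2:
    def test_single_predictor_matches_plain_fit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        inc = w.incremental_r2(y, pd.DataFrame({"x": x}))
        plain = w.ols_fit(y, x)
        assert inc.table["cum_adj_r2"].iloc[0] == pytest.approx(plain.adj_r2)

    def test_last_cumulative_equals_full_adj_r2(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = X @ [1.0, 0.5, 0.0, -0.3] + rng.normal(size=200)
        rep = w.incremental_r2(y, X)
        assert rep.table["cum_adj_r2"].iloc[-1] == pytest.approx(rep.adj_r2, rel=1e-12)
        # nested-model oracle: each cumulative value is its own full fit
        for k in range(1, 5):
            assert rep.table["cum_adj_r2"].iloc[k - 1] == pytest.approx(
                w.ols_fit(y, X.iloc[:, :k]).adj_r2, rel=1e-12
            )

    def test_betas_come_from_full_model(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(150, 2)), columns=["a", "b"])
        X["b"] += 0.6 * X["a"]  # correlated, so marginal != partial betas
        y = X @ [1.0, 1.0] + rng.normal(size=150)
        rep = w.incremental_r2(y, X)
        full = w.ols_fit(y, X)
        np.testing.assert_allclose(rep.table["beta"], full.table["beta"])
        marginal_a = w.ols_fit(y, X[["a"]]).table["beta"].iloc[0]
        assert rep.table["beta"].iloc[0] != pytest.approx(marginal_a, rel=1e-3)


class TestWelchFromSummary:
    def test_identity_with_raw_welch(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 2, 55)
        t, df, p = w.welch_t_from_summary(
            a.mean(), a.std(ddof=1), 40, b.mean(), b.std(ddof=1), 55
        )
        raw = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(raw.statistic, rel=1e-12)
        assert p == pytest.approx(raw.pvalue, rel=1e-12)
        assert df == pytest.approx(raw.df, rel=1e-12)

    def test_pooled_identity_with_raw_student(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.2, 1, 30)
        t, df, p = w.welch_t_from_summary(
            a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 30, pooled=True
        )
        raw = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(raw.statistic, rel=1e-12)
        assert df == 58
        assert p == pytest.approx(raw.pvalue, rel=1e-12)

    def test_hand_computed_example(self):
        # t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
        t, df, p = w.welch_t_from_summary(10.0, 2.0, 50, 11.0, 2.0, 50)
        assert t == pytest.approx(-1.0 / np.sqrt(2 * 4 / 50), rel=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            w.welch_t_from_summary(1, 0, 10, 2, 0, 10)
        with pytest.raises(ValidationError):
            w.welch_t_from_summary(1, 1, 1, 2, 1, 10)


class TestAnovaFromSummary:
    def test_identity_with_raw_f_oneway(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1.2, n) for m, n in [(0, 30), (0.4, 45), (0.1, 25)]]
        labels = np.repeat(["a", "b", "c"], [30, 45, 25])
        f, df1, df2, p = w.anova_from_summary(
            w.summaries(np.concatenate(groups), labels)
        )
        raw = stats.f_oneway(*groups)
        assert f == pytest.approx(raw.statistic, rel=1e-10)
        assert p == pytest.approx(raw.pvalue, rel=1e-10)
        assert (df1, df2) == (2, 97)

    def test_equal_means_f_zero(self):
        gs = [w.GroupSummary(str(i), 20, 5.0, 1.0) for i in range(3)]
        f, _, _, p = w.anova_from_summary(gs)
        assert f == 0.0 and p == 1.0

    def test_two_groups_f_equals_pooled_t_squared(self):
        g1 = w.GroupSummary("a", 40, 10.0, 2.0)
        g2 = w.GroupSummary("b", 35, 11.2, 2.4)
        f, _, df2, pf = w.anova_from_summary([g1, g2])
        t, dft, pt = w.welch_t_from_summary(10.0, 2.0, 40, 11.2, 2.4, 35, pooled=True)
        assert f == pytest.approx(t**2, rel=1e-12)
        assert pf == pytest.approx(pt, rel=1e-12)
        assert df2 == dft

    def test_zero_within_variance_rejected(self):
        gs = [w.GroupSummary("a", 10, 1.0, 0.0), w.GroupSummary("b", 10, 2.0, 0.0)]
        with pytest.raises(DegenerateDataError):
            w.anova_from_summary(gs)


class TestPairedT:
    def test_hand_computation(self):
        before = np.array([100.0, 90.0, 80.0, 95.0])
        after = np.array([98.0, 89.0, 81.0, 92.0])
        t, df, p = w.paired_t(before, after)
        d = after - before
        t_hand = d.mean() / (d.std(ddof=1) / 2.0)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == 3

    def test_detects_small_systematic_loss(self):
        # a ~1% mean drop on a 5% within-subject sd is detectable at n=400
        rng = np.random.default_rng(9)
        before = rng.normal(90, 12, 400)
        after = before * (1 - 0.011) + rng.normal(0, 1.0, 400)
        t, _, p = w.paired_t(before, after)
        assert t < 0 and p < 1e-6

    def test_constant_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            w.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            w.paired_t([1.0, 2.0], [1.0])


class TestKruskalWallis:
    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, 30) for m in (0, 0.5, 1.0, 0.2)]
        h, df, p = w.kruskal_wallis(*groups)
        raw = stats.kruskal(*groups)
        assert h == pytest.approx(raw.statistic)
        assert p == pytest.approx(raw.pvalue)
        assert df == 3

    def test_null_uniform_p(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            ps.append(w.kruskal_wallis(rng.normal(size=25), rng.normal(size=25))[2])
        assert 0.25 < np.mean(np.array(ps) < 0.5) < 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            w.kruskal_wallis([1.0, 2.0], [])

    def test_constant_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            w.kruskal_wallis([3.0, 3.0], [3.0, 3.0])


class TestSummaries:
    def test_matches_numpy_groupwise(self):
        v = np.array([1.0, 2.0, 3.0, 10.0, 12.0])
        labs = np.array(["a", "a", "a", "b", "b"])
        gs = {g.label: g for g in w.summaries(v, labs)}
        assert gs["a"].mean == pytest.approx(2.0)
        assert gs["a"].sd == pytest.approx(1.0)
        assert gs["b"].n == 2

    def test_invalid_group_summary_rejected(self):
        with pytest.raises(ValidationError):
            w.GroupSummary("x", 1, 0.0, 1.0)
        with pytest.raises(ValidationError):
            w.GroupSummary("x", 5, 0.0, -1.0)
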