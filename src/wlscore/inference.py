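"""Adjusted regressions, incremental variance decomposition and group tests.

The centrepiece is the incremental adjusted-R² table: predictors are added
one at a time in a fixed order, the adjusted ("corrected") R² of each nested
model is recorded, and the per-predictor coefficients, confidence intervals
and p-values are taken from the FULL model — the layout used when reporting
how much weight-change variance a genetic score explains on top of baseline
weight and demographics.

Group tests come in raw-data and summary-statistic forms.  The summary
forms (Welch/pooled t from mean/sd/n pairs, one-way ANOVA rebuilt from the
between/within sum-of-squares decomposition) exist so that published group
summaries can be checked directly without raw data; they are exact
identities of their raw-data counterparts when the summaries are computed
from the raw sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError, FitError, ValidationError


@dataclass
class GroupSummary:
    """Sufficient statistics (n, mean, sd) for one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValidationError(f"group {self.label!r}: sd must be >= 0")


@dataclass
class RegressionReport:
    """Coefficients beside cumulative adjusted R² of the nested models."""

    table: pd.DataFrame  # predictor, beta, ci_low, ci_high, p, cum_adj_r2
    n: int
    r2: float
    adj_r2: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def _as_design(predictors) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(dtype=float), list(predictors.columns)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i + 1}" for i in range(X.shape[1])]


def ols_fit(outcome, predictors) -> RegressionReport:
    """Least-squares fit with classical SEs, p-values and adjusted R²."""
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(predictors)
    n, p = X.shape
    if n <= p + 1:
        raise FitError(f"n = {n} too small for {p} predictors")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the columns involved in the collinearity, if identifiable
        suspects = []
        for j in range(X.shape[1]):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                suspects.append(names[j])
        raise FitError(f"rank-deficient design; collinear columns: {suspects or names}")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "predictor": names,
            "beta": res.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": res.pvalues[1:],
            "cum_adj_r2": np.nan,
        }
    )
    table.loc[table.index[-1], "cum_adj_r2"] = res.rsquared_adj
    return RegressionReport(table=table, n=n, r2=float(res.rsquared), adj_r2=float(res.rsquared_adj))


def incremental_r2(outcome, predictors: pd.DataFrame) -> RegressionReport:
    """Nested-model adjusted R² as predictors are added in column order.

    The cumulative column holds the adjusted R² after adding each predictor;
    betas, CIs and p-values are from the full model.  The last cumulative
    value equals the full model's adjusted R² by construction.
    """
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame(_as_design(predictors)[0], columns=_as_design(predictors)[1])
    full = ols_fit(outcome, predictors)
    cum = []
    for k in range(1, predictors.shape[1] + 1):
        step = ols_fit(outcome, predictors.iloc[:, :k])
        cum.append(step.adj_r2)
    table = full.table.copy()
    table["cum_adj_r2"] = cum
    return RegressionReport(table=table, n=full.n, r2=full.r2, adj_r2=full.adj_r2)


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from (mean, sd, n) summaries.

    Default is Welch with Satterthwaite df; ``pooled=True`` gives the
    classical equal-variance Student test.  Returns (t, df, p) two-sided.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValidationError("sd must be >= 0")
    if s1 == 0 and s2 == 0:
        raise DegenerateDataError("both SDs are zero; t-test degenerate")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=pooled)
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def summaries(values, labels=None) -> list[GroupSummary]:
    """Per-group (n, mean, sample sd) from raw values."""
    v = np.asarray(values, dtype=float)
    if labels is None:
        return [GroupSummary("all", v.size, float(v.mean()), float(v.std(ddof=1)))]
    labels = np.asarray(labels)
    out = []
    for lab in dict.fromkeys(labels.tolist()):
        x = v[labels == lab]
        out.append(GroupSummary(str(lab), x.size, float(x.mean()), float(x.std(ddof=1))))
    return out


def anova_from_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA rebuilt from group summaries.

    Between-group SS from means and sizes, within-group SS from the sample
    SDs; identical to the raw-data F test when summaries come from the raw
    sample.  Returns (F, df_between, df_within, p).
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_tot = ns.sum()
    grand = (ns * means).sum() / n_tot
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1 = len(groups) - 1
    df2 = int(n_tot) - len(groups)
    if ss_within == 0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def paired_t(before, after) -> tuple[float, int, float]:
    """Paired t-test on before/after measurements."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValidationError("before/after must be equal-length vectors")
    if b.size < 2:
        raise ValidationError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise DegenerateDataError("constant differences; paired t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), b.size - 1, float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction over >= 2 groups."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group passed to kruskal_wallis")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateDataError("all values identical; rank test undefined")
    res = stats.kruskal(*arrays)
    return float(res.statistic), len(groups) - 1, float(res.pvalue)
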