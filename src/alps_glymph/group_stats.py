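"""Group-comparison and correlation statistics.

The descriptive/inferential battery applied to the four-group cohort:
normality-gated summaries (mean +/- sd vs median (IQR)), one-way ANOVA
(from raw data or published summary moments), covariate-adjusted general
linear models with Bonferroni post hoc contrasts, Kruskal-Wallis tests,
chi-square and Fisher exact tests for categorical variables, and Pearson
and partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "GroupSummary",
    "summarize_groups",
    "anova_oneway",
    "anova_from_summary",
    "glm_adjusted",
    "kruskal_wallis",
    "chi_square_test",
    "fisher_exact",
    "pearson_corr",
    "partial_corr",
]


@dataclass
class StatResult:
    """A test statistic with its degrees of freedom, p-value and post hoc table."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: pd.DataFrame | None = None
    covariates: tuple = ()
    extra: dict = field(default_factory=dict)


@dataclass
class GroupSummary:
    """Per-group descriptives, formatted per the normality verdict."""

    variable: str
    normal: bool
    shapiro_w: float
    shapiro_p: float
    table: pd.DataFrame  # index: group; columns depend on verdict


def summarize_groups(
    cohort: pd.DataFrame, variable: str, by: str = "group", alpha: float = 0.05
) -> GroupSummary:
    """Describe a variable per group, gated by a Shapiro-Wilk normality test.

    Normal variables (pooled-residual Shapiro-Wilk p >= alpha) are reported
    as n/mean/sd, others as n/median/IQR.
    """
    x = cohort[variable].astype(float)
    resid = x - cohort.groupby(by)[variable].transform("mean")
    w, p = stats.shapiro(resid.dropna())
    normal = p >= alpha
    rows = {}
    for g, sub in cohort.groupby(by, sort=False):
        v = sub[variable].astype(float).dropna()
        if normal:
            rows[g] = {"n": len(v), "mean": v.mean(), "sd": v.std(ddof=1)}
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows[g] = {"n": len(v), "median": med, "iqr": q3 - q1}
    return GroupSummary(
        variable=variable,
        normal=bool(normal),
        shapiro_w=float(w),
        shapiro_p=float(p),
        table=pd.DataFrame(rows).T,
    )


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("at least two groups are required")
    return gs


def anova_oneway(groups) -> StatResult:
    """Classic one-way between/within ANOVA on raw group vectors."""
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in gs], dtype=float)
    means = np.array([g.mean() for g in gs])
    sds = np.array([g.std(ddof=1) for g in gs])
    if np.all(sds == 0):
        raise ValueError("zero within-group variance in every group; F undefined")
    return _anova_decomposition(ns, means, sds, test="anova_oneway")


def anova_from_summary(ns, means, sds) -> StatResult:
    """One-way ANOVA from sufficient statistics (n, mean, sd per group).

    Uses the between/within decomposition
    ``SSB = sum n_i (m_i - grand)^2``, ``SSW = sum (n_i - 1) s_i^2``,
    ``F = (SSB/(k-1)) / (SSW/(N-k))`` — identical to the raw-data ANOVA,
    and applicable to published summary tables.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape) or ns.size < 2:
        raise ValueError("ns, means, sds must be equal-length vectors of >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be >= 0")
    return _anova_decomposition(ns, means, sds, test="anova_from_summary")


def _anova_decomposition(ns, means, sds, test: str) -> StatResult:
    k = len(ns)
    n_total = ns.sum()
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ssb / df1) / (ssw / df2)
    return StatResult(
        test=test,
        statistic=float(f),
        df=(int(df1), int(df2)),
        p_value=float(stats.f.sf(f, df1, df2)),
    )


def glm_adjusted(outcome, group, covariates=None, covariate_names=None) -> StatResult:
    """Covariate-adjusted group comparison via a general linear model.

    Fits ``outcome ~ group dummies + covariates`` by least squares; the
    overall group effect is the nested-model F comparing against
    ``outcome ~ covariates``. Pairwise contrasts of adjusted group means
    are Bonferroni-corrected with multiplier ``m = k(k-1)/2``. With no
    covariates this reduces exactly to the one-way ANOVA.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    g = pd.Series(group).astype(str).reset_index(drop=True)
    levels = list(dict.fromkeys(g))  # preserve first-appearance order
    if len(levels) < 2:
        raise ValueError("at least two groups are required")
    dummies = pd.get_dummies(g, dtype=float)[levels].iloc[:, 1:]  # first level = reference

    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        cov = np.empty((len(y), 0))
        covariate_names = ()
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        covariate_names = tuple(covariate_names or [f"cov{i}" for i in range(cov.shape[1])])

    x_full = np.column_stack([np.ones(len(y)), dummies.to_numpy(), cov])
    names = ["intercept"] + [f"group[{lv}]" for lv in levels[1:]] + list(covariate_names)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(f"collinear design matrix (columns: {names})")

    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(len(y)), cov])).fit()
    f, p, df_num = full.compare_f_test(reduced)

    # pairwise contrasts of adjusted means = differences of group dummy coefs
    k = len(levels)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(x_full.shape[1])
            if i > 0:
                c[i] = -1.0  # dummy columns start at index 1
            if j > 0:
                c[j] = 1.0
            t = full.t_test(c)
            praw = float(np.squeeze(t.pvalue))
            rows.append(
                {
                    "contrast": f"{levels[j]} - {levels[i]}",
                    "estimate": float(np.squeeze(t.effect)),
                    "se": float(np.squeeze(t.sd)),
                    "p_raw": praw,
                    "p_bonferroni": min(1.0, m * praw),
                }
            )
    return StatResult(
        test="glm_adjusted",
        statistic=float(f),
        df=(int(df_num), int(full.df_resid)),
        p_value=float(p),
        posthoc=pd.DataFrame(rows),
        covariates=covariate_names,
        extra={"adjusted_means_reference": levels[0], "bonferroni_m": m},
    )


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis rank test with tie correction (chi-square approximation)."""
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations tied; H undefined")
    h, p = stats.kruskal(*gs)
    return StatResult(test="kruskal_wallis", statistic=float(h), df=(len(gs) - 1,), p_value=float(p))


def chi_square_test(table) -> StatResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("table must be a 2D array of nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    low_expected = int(np.count_nonzero(expected < 5))
    return StatResult(
        test="chi_square",
        statistic=float(chi2),
        df=(int(dof),),
        p_value=float(p),
        extra={"expected": expected, "n_expected_below_5": low_expected},
    )


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher exact test for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables no more
    probable than the observed one (the standard two-sided convention).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("fisher_exact requires a 2x2 table of nonnegative integers")
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return StatResult(
        test="fisher_exact",
        statistic=float(odds),
        df=(),
        p_value=float(p),
        extra={"statistic_is_odds_ratio": True},
    )


def pearson_corr(x, y) -> StatResult:
    """Pearson correlation with the t-based p-value on n-2 df."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return StatResult(test="pearson", statistic=float(r), df=(x.size - 2,), p_value=float(p))


def partial_corr(x, y, covariates) -> StatResult:
    """Partial correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept) by
    least squares; the Pearson correlation of the residuals is tested on
    ``n - 2 - q`` degrees of freedom, q the number of covariates.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(covariates, dtype=float)
    if z.size == 0:
        return pearson_corr(x, y)
    if z.ndim == 1:
        z = z[:, None]
    n, q = z.shape
    if not (x.size == y.size == n):
        raise ValueError("x, y and covariates must share the sample dimension")
    if n <= q + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    # relative floor: a variable lying exactly in the covariate span leaves
    # only round-off in its residuals, which carries no correlation signal
    if np.std(rx) <= 1e-12 * max(np.std(x), 1.0) or np.std(ry) <= 1e-12 * max(np.std(y), 1.0):
        raise ValueError("zero residual variance after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(
        test="partial_corr", statistic=r, df=(df,), p_value=float(p), covariates=(q,)
    )
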