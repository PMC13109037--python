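"""Nonparametric group comparison and association statistics.

The comparison layer is rank based throughout: two-sided Mann-Whitney /
Wilcoxon rank-sum tests with Benjamini-Hochberg false-discovery-rate
adjustment within declared test families, Cliff's delta dominance effect
sizes with normal-approximation confidence intervals, boxplot outlier
screening, a two-group ANCOVA with an age covariate, tied-rank transforms,
and partial Spearman correlations (rank residualization against covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MannWhitneyResult:
    u: float  #: Mann-Whitney U for the first sample
    w: float  #: rank-sum W of the first sample (U + n_a(n_a+1)/2)
    p: float


@dataclass
class ComparisonResult:
    """One row of a group-comparison table (the median/IQR/p/delta shape)."""

    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    u: float
    w: float
    p: float
    delta: float
    ci_low: float
    ci_high: float
    p_adj: float = np.nan
    family: str = ""


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p: float
    n: int
    covariates: tuple[str, ...] = field(default_factory=tuple)
    p_adj: float = np.nan


def boxplot_outlier_mask(values: np.ndarray) -> np.ndarray:
    """True for values inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (closed interval).

    Quartiles use linear interpolation. Requires at least 4 values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise ValueError("need at least 4 values for boxplot outlier screening")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def tiedrank(values: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n; ties share the average of their rank span."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return stats.rankdata(values, method="average")


def mann_whitney_test(a: np.ndarray, b: np.ndarray) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; statistic reported as U and rank-sum W.

    Uses exact enumeration for small tie-free samples (both n <= 20),
    otherwise the normal approximation with tie and continuity correction.
    Fully tied data yield p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n_a = len(a)
    w_offset = n_a * (n_a + 1) / 2.0
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        u = len(a) * len(b) / 2.0
        return MannWhitneyResult(u=u, w=u + w_offset, p=1.0)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n_a + len(b)
    method = "exact" if (max(n_a, len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), w=float(res.statistic) + w_offset, p=float(res.pvalue))


def bh_fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(~np.isfinite(pvals)) or np.any(pvals < 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def cliffs_delta(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Cliff's dominance delta with a (1 - alpha) confidence interval.

    delta = [#(a_i > b_j) - #(a_i < b_j)] / (n_a n_b), positive when the
    first group is stochastically larger. The CI uses Cliff's consistent
    variance estimate of the dominance means with a normal critical value,
    truncated to [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    n_a, n_b = len(a), len(b)
    dominance = np.sign(a[:, None] - b[None, :])
    delta = dominance.mean()
    d_rows = dominance.mean(axis=1)
    d_cols = dominance.mean(axis=0)
    num = (
        n_b**2 * np.sum((d_rows - delta) ** 2)
        + n_a**2 * np.sum((d_cols - delta) ** 2)
        - np.sum((dominance - delta) ** 2)
    )
    var = max(num / (n_a * n_b * (n_a - 1) * (n_b - 1)), 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(delta), float(max(delta - half, -1.0)), float(min(delta + half, 1.0))


def ancova_group_age(
    y: np.ndarray, group: np.ndarray, age: np.ndarray
) -> tuple[float, float, dict[str, float]]:
    """Two-group ANCOVA: y ~ intercept + group + age; F test on group.

    Returns (F, p, adjusted means), the adjusted means being model
    predictions per group at the grand mean age. With a single factor of two
    levels the type-III F on the group term equals the squared t of its
    coefficient.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    counts = [int((group == g).sum()) for g in levels]
    if min(counts) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.ptp(age) == 0:
        raise ValueError("age does not vary; design is collinear")
    indicator = (group == levels[1]).astype(float)
    X = np.column_stack([np.ones(len(y)), indicator, age])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear design (group indicator and age)")
    if np.ptp(y) == 0:
        return 0.0, 1.0, {g: float(y[0]) for g in levels}

    fit = sm.OLS(y, X).fit()
    t_group = fit.tvalues[1]
    f_group = float(t_group**2)
    p_group = float(fit.pvalues[1])
    mean_age = age.mean()
    adjusted = {
        levels[0]: float(fit.params[0] + fit.params[2] * mean_age),
        levels[1]: float(fit.params[0] + fit.params[1] + fit.params[2] * mean_age),
    }
    return f_group, p_group, adjusted


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are tied-rank transformed; ranked x and y are residualized
    on the ranked covariates (with intercept) by least squares and the
    Pearson correlation of the residuals is returned, with p from the t
    approximation on n - 2 - n_covariates degrees of freedom. With no
    covariates this reduces exactly to the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must not be constant")
    n = len(x)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations for {k} covariates")

    rx = tiedrank(x)
    ry = tiedrank(y)
    design = np.column_stack(
        [np.ones(n)] + [tiedrank(covariates[:, j]) for j in range(k)]
    )
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    res_x = rx - design @ beta_x
    res_y = ry - design @ beta_y
    denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
    if denom == 0:
        raise ValueError("a variable is fully explained by the covariates")
    rho = float(np.clip(res_x @ res_y / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        var_x=names[0], var_y=names[1], rho=rho, p=p, n=n,
        covariates=tuple(covariate_names),
    )


def compare_groups_table(
    values: pd.DataFrame,
    groups: pd.Series,
    family: str = "",
    remove_outliers: bool = False,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Mann-Whitney + Cliff's delta per column, BH-adjusted within the family.

    ``values`` is subjects x variables aligned with ``groups`` (two levels;
    the alphabetically first level is the "first" group for the delta sign).
    Missing cells are dropped per variable; with ``remove_outliers`` each
    group is additionally screened by the boxplot rule before testing.
    """
    if not values.index.equals(groups.index):
        raise ValueError("values and groups are not aligned on subjects")
    levels = sorted(pd.unique(groups.dropna()).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    results = []
    for variable in values.columns:
        col = values[variable]
        samples = {}
        for level in levels:
            sample = col[groups == level].dropna().to_numpy(dtype=float)
            if remove_outliers:
                sample = sample[boxplot_outlier_mask(sample)]
            samples[level] = sample
        a, b = samples[levels[0]], samples[levels[1]]
        test = mann_whitney_test(a, b)
        delta, lo, hi = cliffs_delta(a, b, alpha=alpha)
        q1a, med_a, q3a = np.percentile(a, [25, 50, 75])
        q1b, med_b, q3b = np.percentile(b, [25, 50, 75])
        results.append(
            ComparisonResult(
                variable=str(variable),
                group_a=levels[0], group_b=levels[1],
                n_a=len(a), n_b=len(b),
                median_a=float(med_a), iqr_a=float(q3a - q1a),
                median_b=float(med_b), iqr_b=float(q3b - q1b),
                u=test.u, w=test.w, p=test.p,
                delta=delta, ci_low=lo, ci_high=hi,
                family=family,
            )
        )
    adjusted = bh_fdr_adjust(np.array([r.p for r in results]))
    for result, p_adj in zip(results, adjusted):
        result.p_adj = float(p_adj)
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a table (Table-2-style columns)."""
    return pd.DataFrame([vars(r) for r in results])


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = vars(r).copy()
        row["covariates"] = ",".join(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
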