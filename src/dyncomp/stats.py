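"""Patient-level outcome construction and the hypothesis-testing layer.

Outcomes are relative change scores (negative = improvement):

    relative change = (post - pre) / pre * 100

computed from pre/post Y-BOCS totals and from first-week vs last-week means
of the symptom-severity factor of the daily process ratings.  The testing
layer provides Pearson correlations, a median-split 2x2 ANOVA with Type III
sums of squares and partial eta squared, pooled-variance post-hoc t-tests
with Cohen's d, and block-wise hierarchical OLS regression with standardized
coefficients, R-squared change and F-change per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core_data import RatingSeries

__all__ = [
    "OutcomeRecord",
    "CorrelationResult",
    "MedianSplit",
    "AnovaEffect",
    "TwoSampleTestReport",
    "BlockResult",
    "relative_change",
    "weekly_symptom_means",
    "correlate",
    "median_split",
    "anova_2x2",
    "posthoc_t",
    "hierarchical_regression",
]


@dataclass
class OutcomeRecord:
    patient_id: str
    ybocs_pre: float
    ybocs_post: float
    tpq_sym_pre: float
    tpq_sym_post: float

    @property
    def rel_ybocs_change(self) -> float:
        return relative_change(self.ybocs_pre, self.ybocs_post)

    @property
    def rel_tpq_change(self) -> float:
        return relative_change(self.tpq_sym_pre, self.tpq_sym_post)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class MedianSplit:
    labels: np.ndarray  # 'low' / 'high'
    median: float
    n_low: int
    n_high: int


@dataclass
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass
class TwoSampleTestReport:
    t: float
    df: float
    p: float
    cohen_d: float
    n1: int
    n2: int


@dataclass
class BlockResult:
    block: int
    predictors: list[str]
    beta: dict[str, float]  # standardized coefficients
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float
    r_squared_change: float
    f_change: float
    p_change: float
    n: int


def relative_change(pre: float, post: float) -> float:
    """Percent change from pre to post: (post - pre) / pre * 100."""
    if pre <= 0:
        raise ValueError(f"pre score must be positive, got {pre}")
    return (post - pre) / pre * 100.0


def weekly_symptom_means(
    factor_series: RatingSeries, min_days: int = 3
) -> tuple[float, float]:
    """Mean of the first and last 7 calendar days of a factor score series.

    Each week must contain at least ``min_days`` non-missing values; the
    series must span at least 14 days so the weeks cannot overlap.
    """
    days, values = factor_series.days, factor_series.values
    span = days.max() - days.min() + 1
    if span < 14:
        raise ValueError(f"series spans only {span} days; need >= 14")
    first = (days <= days.min() + 6) & ~np.isnan(values)
    last = (days >= days.max() - 6) & ~np.isnan(values)
    if first.sum() < min_days:
        raise ValueError(f"first week has only {int(first.sum())} observed days")
    if last.sum() < min_days:
        raise ValueError(f"last week has only {int(last.sum())} observed days")
    return float(values[first].mean()), float(values[last].mean())


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with two-sided p (t distribution, n-2 df), listwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def median_split(values: np.ndarray) -> MedianSplit:
    """Dichotomize at the sample median; ties at the median go to the low group."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for a median split")
    if np.isnan(values).any():
        raise ValueError("median split requires complete values")
    med = float(np.median(values))
    labels = np.where(values <= med, "low", "high")
    n_low = int(np.sum(labels == "low"))
    n_high = values.size - n_low
    if n_high == 0:
        raise ValueError("all values are at or below the median; no split possible")
    return MedianSplit(labels=labels, median=med, n_low=n_low, n_high=n_high)


def anova_2x2(
    outcome: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> dict[str, AnovaEffect]:
    """Two-way fixed-effects ANOVA with interaction, Type III sums of squares.

    Unbalanced cells are allowed (Type III with sum-to-zero contrasts keeps
    main effects interpretable in the presence of the interaction); empty
    cells are an error.  partial eta^2 = SS_effect / (SS_effect + SS_error).
    Returns effects keyed 'a', 'b', 'a:b'.
    """
    df = pd.DataFrame(
        {"y": np.asarray(outcome, dtype=float),
         "a": np.asarray(factor_a).astype(str),
         "b": np.asarray(factor_b).astype(str)}
    ).dropna()
    counts = df.groupby(["a", "b"]).size()
    levels_a, levels_b = df["a"].unique(), df["b"].unique()
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("each factor must have exactly 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty cell: a={la!r}, b={lb!r}")
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = anova_lm(model, typ=3)
    y = df["y"].to_numpy()
    ss_total = float(((y - y.mean()) ** 2).sum())
    tiny = 1e-12 * max(ss_total, 1.0)  # numerically-null SS (zero-noise designs)
    ss_err = float(table.loc["Residual", "sum_sq"])
    ss_err = 0.0 if ss_err < tiny else ss_err
    df_err = int(table.loc["Residual", "df"])
    out: dict[str, AnovaEffect] = {}
    name_map = {"C(a, Sum)": "a", "C(b, Sum)": "b", "C(a, Sum):C(b, Sum)": "a:b"}
    for row_name, key in name_map.items():
        ss = float(table.loc[row_name, "sum_sq"])
        ss = 0.0 if ss < tiny else ss
        df_num = int(table.loc[row_name, "df"])
        if ss == 0.0:
            F, p = 0.0, 1.0
        elif ss_err == 0.0:
            F, p = float("inf"), 0.0
        else:
            F = (ss / df_num) / (ss_err / df_err)
            p = float(sps.f.sf(F, df_num, df_err))
        out[key] = AnovaEffect(
            F=F,
            df_num=df_num,
            df_den=df_err,
            p=p,
            partial_eta_sq=ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
        )
    return out


def posthoc_t(
    group1: np.ndarray, group2: np.ndarray, welch: bool = False
) -> TwoSampleTestReport:
    """Two-sample t-test with Cohen's d (pooled-sd by default, Welch optional)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(g1, g2, equal_var=not welch)
    if welch:
        v1, v2 = g1.var(ddof=1) / n1, g2.var(ddof=1) / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = float(n1 + n2 - 2)
    d = (g1.mean() - g2.mean()) / np.sqrt(pooled_var)
    return TwoSampleTestReport(
        t=float(res.statistic), df=df, p=float(res.pvalue), cohen_d=float(d), n1=n1, n2=n2
    )


def hierarchical_regression(
    outcome: np.ndarray, blocks: list[tuple[str, dict[str, np.ndarray]]]
) -> list[BlockResult]:
    """Block-wise hierarchical OLS: nested models grown one block at a time.

    ``blocks`` is an ordered list of (block_name, {predictor: values}); each
    block's model contains all predictors of the preceding blocks plus its
    own.  Coefficients are standardized (all variables z-scored), so beta is
    on the correlation scale; R^2 change and its F test quantify the added
    block's contribution:

        F_change = dR^2 * (n - p_k - 1) / ((1 - R^2_k) * q_k)

    with p_k total and q_k newly added predictors in block k.
    """
    y = np.asarray(outcome, dtype=float)
    all_predictors: dict[str, np.ndarray] = {}
    for _, preds in blocks:
        for name, vals in preds.items():
            all_predictors[name] = np.asarray(vals, dtype=float)
    X_all = np.column_stack(list(all_predictors.values())) if all_predictors else None
    if X_all is None:
        raise ValueError("no predictors supplied")
    mask = ~np.isnan(y) & ~np.isnan(X_all).any(axis=1)
    y = y[mask]
    n = y.size
    names_so_far: list[str] = []
    results: list[BlockResult] = []
    r2_prev = 0.0
    for k, (_, preds) in enumerate(blocks, start=1):
        new_names = list(preds.keys())
        names_so_far = names_so_far + new_names
        p_k, q_k = len(names_so_far), len(new_names)
        if n < p_k + 2:
            raise ValueError(f"only {n} complete cases for {p_k} predictors")
        Xz = np.column_stack(
            [_zscore(all_predictors[name][mask], name) for name in names_so_far]
        )
        yz = _zscore(y, "outcome")
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xz])) < p_k + 1:
            raise ValueError(f"rank-deficient design in block {k}: {names_so_far}")
        fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
        r2 = float(fit.rsquared)
        dr2 = r2 - r2_prev
        if r2 < 1.0:
            f_change = dr2 * (n - p_k - 1) / ((1.0 - r2) * q_k)
            p_change = float(sps.f.sf(f_change, q_k, n - p_k - 1))
        else:  # saturated fit
            f_change, p_change = float("inf"), 0.0
        results.append(
            BlockResult(
                block=k,
                predictors=list(names_so_far),
                beta={nm: float(fit.params[i + 1]) for i, nm in enumerate(names_so_far)},
                t={nm: float(fit.tvalues[i + 1]) for i, nm in enumerate(names_so_far)},
                p={nm: float(fit.pvalues[i + 1]) for i, nm in enumerate(names_so_far)},
                r_squared=r2,
                r_squared_change=dr2,
                f_change=float(f_change),
                p_change=p_change,
                n=n,
            )
        )
        r2_prev = r2
    return results


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in {name}")
    return (values - values.mean()) / sd
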