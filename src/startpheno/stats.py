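"""Group-comparison and reliability statistics.

One-way fixed-effects ANOVA in both raw-data and summary-statistic form
(the latter reproduces printed F values directly from per-group n/mean/SD
rows), partial eta-squared, Bonferroni-adjusted pairwise post hocs with the
pooled error variance, robust alternatives (Welch, Brown-Forsythe,
Kruskal-Wallis) with an assumption-check dispatcher, Pearson chi-square of
independence, and the two-way mixed-effects absolute-agreement
single-measure intraclass correlation ICC(A,1) with its F-based p value and
95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Group, GroupSummary

__all__ = [
    "AnovaResult",
    "IccResult",
    "DegenerateDataError",
    "anova_from_summary",
    "anova_oneway",
    "partial_eta_squared",
    "bonferroni_posthoc",
    "welch_anova",
    "brown_forsythe",
    "kruskal_wallis",
    "levene",
    "normality_check",
    "compare_groups",
    "chi_square_independence",
    "icc_a1",
    "group_table",
    "TABLE3_MEASURES",
]


class DegenerateDataError(ValueError):
    """All-constant input: the requested statistic is undefined."""


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2p: float
    ms_within: float = float("nan")
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class IccResult:
    icc: float
    p: float
    ci95: tuple[float, float]


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """Effect size eta^2_p = F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def _finish(F: float, df_b: int, df_w: int, msw: float) -> AnovaResult:
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        eta2p=partial_eta_squared(F, df_b, df_w),
        ms_within=msw,
    )


def anova_from_summary(summary: GroupSummary) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) triplets.

    Uses the definitional sums of squares: SS_b = sum n_i (m_i - m)^2 with
    the n-weighted grand mean, SS_w = sum (n_i - 1) sd_i^2.
    """
    n = np.array([s[0] for s in summary.stats.values()], dtype=float)
    m = np.array([s[1] for s in summary.stats.values()], dtype=float)
    sd = np.array([s[2] for s in summary.stats.values()], dtype=float)
    grand = float((n * m).sum() / n.sum())
    ss_b = float((n * (m - grand) ** 2).sum())
    ss_w = float(((n - 1) * sd**2).sum())
    df_b = len(n) - 1
    df_w = int(n.sum()) - len(n)
    if ss_w == 0.0 and ss_b == 0.0:
        raise DegenerateDataError(
            f"measure {summary.measure!r}: all groups constant and equal"
        )
    msw = ss_w / df_w
    if msw == 0.0:
        return AnovaResult(
            F=float("inf"), df_between=df_b, df_within=df_w, p=0.0, eta2p=1.0, ms_within=0.0
        )
    return _finish((ss_b / df_b) / msw, df_b, df_w, msw)


def _clean_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for k, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size <= 1:
            raise ValueError(f"group {k!r}: needs n > 1 non-missing values")
        out[str(k)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def anova_oneway(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on raw per-group values."""
    groups = _clean_groups(values_by_group)
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_b = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    if ss_w == 0.0 and ss_b == 0.0:
        raise DegenerateDataError("all groups constant and equal")
    msw = ss_w / df_w
    if msw == 0.0:
        return AnovaResult(
            F=float("inf"), df_between=df_b, df_within=df_w, p=0.0, eta2p=1.0, ms_within=0.0
        )
    return _finish((ss_b / df_b) / msw, df_b, df_w, msw)


def bonferroni_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    msw: Optional[float] = None,
    df_w: Optional[int] = None,
) -> dict[tuple[str, str], float]:
    """Pairwise t tests on the pooled within-group mean square, Bonferroni-adjusted.

    Two-sided p values multiplied by the number of pairs and capped at 1
    (the multiplication-and-cap rule that yields printed adjusted values
    of exactly 1.00 for indistinguishable pairs).
    """
    groups = _clean_groups(values_by_group)
    if msw is None or df_w is None:
        res = anova_oneway(groups)
        msw, df_w = res.ms_within, res.df_within
    pairs = list(combinations(groups, 2))
    out = {}
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        se = np.sqrt(msw * (1.0 / va.size + 1.0 / vb.size))
        if se == 0.0:
            out[(a, b)] = 1.0
            continue
        t = (va.mean() - vb.mean()) / se
        p = 2.0 * float(sps.t.sf(abs(t), df_w))
        out[(a, b)] = min(1.0, p * len(pairs))
    return out


def welch_anova(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, int, float, float]:
    """Welch's heteroscedastic one-way test: (F, df1, df2_adj, p)."""
    groups = _clean_groups(values_by_group)
    k = len(groups)
    n = np.array([v.size for v in groups.values()], dtype=float)
    m = np.array([v.mean() for v in groups.values()])
    var = np.array([v.var(ddof=1) for v in groups.values()])
    w = n / var
    mw = float((w * m).sum() / w.sum())
    A = float((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum() * 3.0 / (k**2 - 1)
    F = A / (1 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    p = float(sps.f.sf(F, k - 1, df2))
    return float(F), k - 1, float(df2), p


def brown_forsythe(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, int, float, float]:
    """Brown-Forsythe robust test of equal means: (F*, df1, df2, p)."""
    groups = _clean_groups(values_by_group)
    k = len(groups)
    n = np.array([v.size for v in groups.values()], dtype=float)
    m = np.array([v.mean() for v in groups.values()])
    var = np.array([v.var(ddof=1) for v in groups.values()])
    grand = float(np.concatenate(list(groups.values())).mean())
    num = float((n * (m - grand) ** 2).sum())
    c = (1 - n / n.sum()) * var
    denom = float(c.sum())
    if denom == 0.0:
        raise DegenerateDataError("zero within-group variance in every group")
    F = num / denom
    df2 = denom**2 / float((c**2 / (n - 1)).sum())
    p = float(sps.f.sf(F, k - 1, df2))
    return float(F), k - 1, float(df2), p


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, int, float]:
    groups = _clean_groups(values_by_group)
    H, p = sps.kruskal(*groups.values())
    return float(H), len(groups) - 1, float(p)


def levene(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Levene/Brown-Forsythe (median-centred) test of homogeneity of variance."""
    groups = _clean_groups(values_by_group)
    W, p = sps.levene(*groups.values(), center="median")
    return float(W), float(p)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test on one sample."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    stat, p = sps.shapiro(arr)
    return float(stat), float(p)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """Classical ANOVA plus assumption checks and robust alternatives.

    Runs Shapiro-Wilk per group and Levene across groups; when an
    assumption fails at ``alpha`` the corresponding robust variant
    (Kruskal-Wallis for non-normality; Welch and Brown-Forsythe for
    heteroscedasticity) is reported alongside, never silently substituted.
    """
    groups = _clean_groups(values_by_group)
    res = anova_oneway(groups)
    res.posthoc = bonferroni_posthoc(groups, res.ms_within, res.df_within)
    shapiro_p = {k: normality_check(v)[1] for k, v in groups.items()}
    lev_W, lev_p = levene(groups)
    out = {
        "anova": res,
        "shapiro_p": shapiro_p,
        "levene": (lev_W, lev_p),
        "normality_violated": any(p < alpha for p in shapiro_p.values()),
        "homogeneity_violated": lev_p < alpha,
    }
    if out["normality_violated"]:
        out["kruskal"] = kruskal_wallis(groups)
    if out["homogeneity_violated"]:
        out["welch"] = welch_anova(groups)
        out["brown_forsythe"] = brown_forsythe(groups)
    return out


def chi_square_independence(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (chi2, df, p)."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def icc_a1(ratings: np.ndarray) -> IccResult:
    """ICC(A,1): two-way mixed model, absolute agreement, single measure.

    ``ratings``: subjects x raters matrix, complete.  Point estimate
    (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n), with the
    standard F-based p value and 95% confidence interval for
    absolute-agreement single-measure coefficients.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 5:
        raise ValueError("need a complete subjects x raters matrix, >=5 x >=2")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        raise DegenerateDataError("zero total variance in ratings")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F test against ICC = 0 and CI (McGraw & Wong absolute-agreement forms)
    if mse == 0.0:
        return IccResult(icc=float(icc), p=0.0, ci95=(float(icc), float(icc)))
    p = float(sps.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_lo = float(sps.f.ppf(0.975, n - 1, v))
    f_up = float(sps.f.ppf(0.975, v, n - 1))
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return IccResult(icc=float(icc), p=p, ci95=(lower, upper))


#: Table-layout measure names -> feature slots, in the group-comparison order.
TABLE3_MEASURES: dict[str, str] = {
    "social_preference": "social_preference",
    "social_choice": "social_choice",
    "wheel_looking": "wheel_looking",
    "motor_rmse": "motor_rmse",
    "fft_gain_x": "fft_gain_x",
    "fft_gain_y": "fft_gain_y",
    "jerk": "jerk",
    "pop_force": "pop_force",
    "pop_dist_x": "pop_dist_x",
    "pop_dist_y": "pop_dist_y",
    "colour_crossings": "colour_crossings",
    "pci_caregiver_sync": "pci_caregiver_sync",
    "pci_child_init": "pci_child_init",
    "questionnaire_score": "questionnaire_score",
}


def group_table(
    features: pd.DataFrame, measures: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-measure group comparison in the printed-table layout.

    ``features`` must carry a ``group`` column plus feature-slot columns
    (missing = NaN).  Each row reports per-group n/mean/SD, F, dfs, eta2p,
    p and the three Bonferroni post hoc p values; a measure with any group
    having n <= 1 is flagged missing.
    """
    measures = dict(measures or TABLE3_MEASURES)
    rows = []
    for name, slot in measures.items():
        row: dict = {"measure": name}
        by_group = {}
        degenerate = False
        for g in Group:
            vals = features.loc[features["group"] == g.value, slot].dropna().to_numpy()
            row[f"n_{g.value}"] = int(vals.size)
            row[f"mean_{g.value}"] = float(vals.mean()) if vals.size else np.nan
            row[f"sd_{g.value}"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            if vals.size <= 1:
                degenerate = True
            by_group[g.value] = vals
        if degenerate:
            row["status"] = "missing"
            rows.append(row)
            continue
        res = anova_oneway(by_group)
        ph = bonferroni_posthoc(by_group, res.ms_within, res.df_within)
        row.update(
            status="ok",
            F=res.F,
            df_between=res.df_between,
            df_within=res.df_within,
            eta2p=res.eta2p,
            p=res.p,
        )
        for (a, b), pv in ph.items():
            row[f"p_{a}_vs_{b}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
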