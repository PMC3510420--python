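"""Group-level statistics on the analysed cohort.

One-way ANOVA across diagnostic groups, a two-factor (diagnosis x centre)
variance partition with Type II sums of squares, Pearson correlations between
retention and cognition, simple regression slopes, and chi-squared tests of
proportions. All p-values are two-sided; no multiplicity correction is
applied; missing values are dropped pairwise per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    ``groups`` labels each observation; at least two groups with two or more
    observations each. Zero within-group variance yields an infinite F.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb = len(samples) - 1
    dfw = values.size - len(samples)
    if ssw == 0:
        return AnovaResult(np.inf, dfb, dfw, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, float(stats.f.sf(F, dfb, dfw)))


@dataclass(frozen=True)
class VariancePartition:
    eta2_a: float
    eta2_b: float
    eta2_interaction: float
    F_a: float
    F_b: float
    F_interaction: float
    p_a: float
    p_b: float
    p_interaction: float
    ss_a: float
    ss_b: float
    ss_interaction: float
    ss_residual: float
    ss_total: float


def _sse(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank from a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _design(*factor_codes: np.ndarray) -> np.ndarray:
    """Intercept + full dummy coding per factor (+ cell dummies last entry
    may be an interaction, passed pre-combined). Rank handled by lstsq."""
    n = factor_codes[0].shape[0]
    cols = [np.ones((n, 1))]
    for codes in factor_codes:
        levels = pd.unique(codes)
        if len(levels) > 1:
            cols.append(np.column_stack([(codes == l).astype(float)
                                         for l in levels[1:]]))
    return np.hstack(cols)


def variance_partition(values, factor_a, factor_b) -> VariancePartition:
    """Two-way fixed-effects GLM with Type II sums of squares and eta².

    SS(A) = SSE(B) - SSE(A+B), SS(B) symmetric, SS(AB) = SSE(A+B) - SSE(full);
    empty cells are tolerated (rank-deficient designs are solved by
    least squares). eta² is each effect's SS over the total SS.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    cell = np.char.add(np.char.add(a.astype(str), "\x1f"), b.astype(str))

    sse_a, _ = _sse(y, _design(a))
    sse_b, _ = _sse(y, _design(b))
    sse_ab, rank_ab = _sse(y, _design(a, b))
    sse_full, rank_full = _sse(y, _design(cell))

    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_a = max(sse_b - sse_ab, 0.0)
    ss_b_ = max(sse_a - sse_ab, 0.0)
    ss_int = max(sse_ab - sse_full, 0.0)
    df_a = len(pd.unique(a)) - 1
    df_b = len(pd.unique(b)) - 1
    df_int = max(rank_full - rank_ab, 0)
    df_resid = y.size - rank_full
    ms_resid = sse_full / df_resid if df_resid > 0 else np.nan

    def ftest(ss, df):
        if df <= 0 or not np.isfinite(ms_resid) or ms_resid == 0:
            return np.nan, np.nan
        F = (ss / df) / ms_resid
        return float(F), float(stats.f.sf(F, df, df_resid))

    F_a, p_a = ftest(ss_a, df_a)
    F_b, p_b = ftest(ss_b_, df_b)
    F_i, p_i = ftest(ss_int, df_int)
    return VariancePartition(
        eta2_a=ss_a / ss_total, eta2_b=ss_b_ / ss_total,
        eta2_interaction=ss_int / ss_total,
        F_a=F_a, F_b=F_b, F_interaction=F_i,
        p_a=p_a, p_b=p_b, p_interaction=p_i,
        ss_a=ss_a, ss_b=ss_b_, ss_interaction=ss_int,
        ss_residual=sse_full, ss_total=ss_total)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def ols_slope(x, y) -> tuple[float, float, float]:
    """Simple least-squares slope with classical SE and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def chi_squared_proportions(counts) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2 x k contingency table, no continuity
    correction."""
    table = np.asarray(counts, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count <= 0")
    return float(chi2), int(df), float(p)


def cohort_report(table: pd.DataFrame, value_col: str = "composite") -> dict:
    """Standard battery of group statistics on an analysed cohort table.

    Expects columns: diagnosis, centre, composite, apoe_e4, mmse,
    verbal_delayed_z, classification. Returns a JSON-ready dict.
    """
    out: dict = {"n": int(len(table))}
    vals = table[value_col].to_numpy(dtype=float)
    res = anova_oneway(vals, table["diagnosis"].to_numpy())
    out["anova_diagnosis"] = {
        "F": res.F, "df": [res.df_between, res.df_within], "p": res.p,
        "group_means": table.groupby("diagnosis")[value_col].mean().to_dict()}
    vp = variance_partition(vals, table["diagnosis"].to_numpy(),
                            table["centre"].to_numpy())
    out["variance_partition"] = {
        "eta2_diagnosis": vp.eta2_a, "eta2_centre": vp.eta2_b,
        "eta2_interaction": vp.eta2_interaction,
        "p_diagnosis": vp.p_a, "p_centre": vp.p_b,
        "p_interaction": vp.p_interaction,
        "ss_type": "II"}
    for col, key in [("verbal_delayed_z", "r_delayed_recall"),
                     ("mmse", "r_mmse")]:
        if col in table:
            r, p, n = pearson_r(vals, table[col].to_numpy(dtype=float))
            out[key] = {"r": r, "p": p, "n": n}
    if "verbal_delayed_z" in table:
        slopes = {}
        for g, sub in table.groupby("diagnosis"):
            try:
                s, se, p = ols_slope(sub[value_col].to_numpy(dtype=float),
                                     sub["verbal_delayed_z"].to_numpy(dtype=float))
                slopes[g] = {"slope": s, "se": se, "p": p}
            except ValueError:
                slopes[g] = None
        out["delayed_recall_slope_by_group"] = slopes
    if "apoe_e4" in table:
        sub = table.dropna(subset=["apoe_e4"])
        tab = pd.crosstab(sub["apoe_e4"].astype(bool), sub["diagnosis"])
        if tab.shape[0] == 2:
            chi2, df, p = chi_squared_proportions(tab.to_numpy())
            out["apoe_by_diagnosis_chi2"] = {"chi2": chi2, "df": df, "p": p}
        mci = sub[sub["diagnosis"] == "mci"]
        if len(mci) > 4 and mci["apoe_e4"].astype(bool).nunique() == 2:
            res = anova_oneway(mci[value_col].to_numpy(dtype=float),
                               mci["apoe_e4"].astype(bool).to_numpy())
            out["apoe_effect_mci"] = {"F": res.F, "p": res.p,
                                      "df": [res.df_between, res.df_within]}
    if "classification" in table:
        rates = {}
        for g, sub in table.groupby("diagnosis"):
            pos = (sub["classification"] == "positive").mean()
            rates[g] = {"percent_positive": 100.0 * pos, "n": int(len(sub))}
        out["positivity"] = rates
    return out
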