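"""Trait-table statistics: normality, correlation, clustering, group tests.

Operates on a "trait table": a pandas DataFrame with one row per plant,
label columns (``species``, ``accession``, ``spike_type``) and one column
per trait abbreviation.  Missing values are allowed and handled
pairwise-complete for correlations, listwise within each test.

Covers the analyses run on such tables in spike-morphometry studies:
Shapiro-Wilk normality scans, Pearson correlation matrices with UPGMA trait
clustering (distance 1 - r), per-trait one-factor ANOVA / Brown-Forsythe
(median-centred Levene) / tie-corrected Kruskal-Wallis group tests,
per-group mean +/- SE summaries with extreme-group flags, and two-accession
comparisons (pooled or Welch t test, two-sided variance-ratio F test,
Mann-Whitney) that also run from printed summary statistics alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .geometry import ALL_TRAIT_NAMES

__all__ = [
    "GroupTestRow",
    "TwoSampleRow",
    "normality_scan",
    "correlation_matrix",
    "pairwise_regression",
    "trait_tree",
    "group_tests",
    "summarize_by_group",
    "compare_accessions",
    "two_sample_from_summary",
    "variance_ratio_test",
]


def _trait_columns(table: pd.DataFrame,
                   traits: Optional[Sequence[str]]) -> List[str]:
    if traits is not None:
        missing = [t for t in traits if t not in table.columns]
        if missing:
            raise KeyError(f"traits not in table: {missing}")
        return list(traits)
    return [c for c in ALL_TRAIT_NAMES if c in table.columns]


def normality_scan(
    table: pd.DataFrame,
    traits: Optional[Sequence[str]] = None,
    group: Optional[str] = None,
) -> pd.DataFrame:
    """Shapiro-Wilk W and p per trait, optionally within each group.

    Vectors with fewer than 3 non-missing values or zero variance are
    flagged (``ok=False``) and reported with NaN statistics.
    """
    cols = _trait_columns(table, traits)
    groups = [(None, table)] if group is None else list(table.groupby(group, observed=True))
    out = []
    for gname, sub in groups:
        for trait in cols:
            x = pd.to_numeric(sub[trait], errors="coerce").dropna().to_numpy()
            row = {"trait": trait, "n": len(x), "W": np.nan, "p": np.nan, "ok": False}
            if group is not None:
                row["group"] = gname
            if len(x) >= 3 and np.ptp(x) > 0:
                w, p = sps.shapiro(x)
                row.update(W=float(w), p=float(p), ok=True)
            out.append(row)
    return pd.DataFrame(out)


def correlation_matrix(
    table: pd.DataFrame, traits: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over trait columns."""
    cols = _trait_columns(table, traits)
    num = table[cols].apply(pd.to_numeric, errors="coerce")
    r = num.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    return r


def pairwise_regression(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """OLS of y on x over complete pairs; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def trait_tree(corr: pd.DataFrame, use_abs: bool = False) -> Tuple[np.ndarray, List[str]]:
    """UPGMA dendrogram of traits from their correlation matrix.

    Agglomerates on distance ``d = 1 - r`` (or ``1 - |r|`` when ``use_abs``)
    by average linkage; returns the scipy linkage matrix and the leaf names.
    Missing correlations are imputed as zero similarity with a warning.
    """
    r = corr.to_numpy(dtype=float).copy()
    if np.isnan(r).any():
        warnings.warn("missing correlations; treating them as r = 0", stacklevel=2)
        r[np.isnan(r)] = 0.0
    if use_abs:
        r = np.abs(r)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    d[d < 0] = 0.0
    Z = linkage(squareform(d, checks=False), method="average")
    return Z, list(corr.columns)


@dataclass(frozen=True)
class GroupTestRow:
    """Per-trait multi-group test results (ANOVA, Brown-Forsythe, Kruskal-Wallis)."""

    trait: str
    anova_F: float
    anova_p: float
    levene_p: float
    kruskal_H: float
    kruskal_p: float


def group_tests(
    table: pd.DataFrame,
    group: str,
    traits: Optional[Sequence[str]] = None,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """One-factor ANOVA, median-centred Levene and Kruskal-Wallis per trait.

    Groups with fewer than ``min_group_size`` complete observations for a
    trait are excluded from that trait's tests with a warning.
    """
    cols = _trait_columns(table, traits)
    out = []
    for trait in cols:
        samples = []
        for gname, sub in table.groupby(group, observed=True):
            x = pd.to_numeric(sub[trait], errors="coerce").dropna().to_numpy()
            if len(x) >= min_group_size:
                samples.append(x)
            elif len(x) > 0:
                warnings.warn(
                    f"group {gname!r} has n={len(x)} for {trait}; excluded",
                    stacklevel=2,
                )
        if len(samples) < 2:
            out.append(GroupTestRow(trait, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        F, p_a = sps.f_oneway(*samples)
        _, p_l = sps.levene(*samples, center="median")
        H, p_k = sps.kruskal(*samples)
        out.append(GroupTestRow(trait, float(F), float(p_a), float(p_l),
                                float(H), float(p_k)))
    return pd.DataFrame([r.__dict__ for r in out])


def summarize_by_group(
    table: pd.DataFrame, group: str, traits: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-group n, mean and standard error per trait, with extreme flags.

    ``flag`` marks, within each trait, the group with the largest mean
    ("max") and the smallest ("min") — mirroring the bold/italic convention
    of printed per-species summary tables.
    """
    cols = _trait_columns(table, traits)
    rows = []
    for gname, sub in table.groupby(group, observed=True):
        for trait in cols:
            x = pd.to_numeric(sub[trait], errors="coerce").dropna().to_numpy()
            n = len(x)
            mean = float(np.mean(x)) if n else np.nan
            se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan)
            rows.append({"group": gname, "trait": trait, "n": n, "mean": mean, "se": se})
    df = pd.DataFrame(rows)
    df["flag"] = ""
    for trait in cols:
        sel = df["trait"] == trait
        means = df.loc[sel, "mean"]
        if means.notna().any():
            df.loc[means.idxmax(), "flag"] = "max"
            df.loc[means.idxmin(), "flag"] = "min"
    return df


def variance_ratio_test(n1: int, var1: float, n2: int, var2: float) -> Tuple[float, float]:
    """Two-sided F test of equal variances from summary statistics.

    Returns (F, p) with F = var1/var2 and p = 2 * min(tail probabilities),
    capped at 1.
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 in both groups")
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be >= 0")
    if var2 == 0:
        if var1 == 0:
            return np.nan, np.nan
        return np.inf, 0.0
    F = var1 / var2
    dist = sps.f(n1 - 1, n2 - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(p, 1.0))


@dataclass(frozen=True)
class TwoSampleRow:
    """Two-accession comparison of one trait."""

    trait: str
    n1: int
    mean1: float
    var1: float
    n2: int
    mean2: float
    var2: float
    t_p: float
    f_p: float
    mw_p: float


def two_sample_from_summary(
    n1: int, mean1: float, var1: float,
    n2: int, mean2: float, var2: float,
    equal_var: bool = True,
) -> Tuple[float, float]:
    """t test of equal means from summary statistics; returns (t, two-sided p).

    ``equal_var=True`` uses the pooled-variance statistic (the convention of
    the desktop statistics packages these comparisons are usually run in);
    ``False`` gives the Welch variant.
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 in both groups")
    if var1 == 0 and var2 == 0:
        return np.nan, np.nan
    res = sps.ttest_ind_from_stats(
        mean1, np.sqrt(var1), n1, mean2, np.sqrt(var2), n2, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def compare_accessions(
    table: Optional[pd.DataFrame] = None,
    accession_a: Optional[str] = None,
    accession_b: Optional[str] = None,
    traits: Optional[Sequence[str]] = None,
    summaries: Optional[Dict[str, Tuple[int, float, float, int, float, float]]] = None,
    accession_column: str = "accession",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-trait two-sample comparison of two accessions.

    Raw mode: pass ``table`` plus the two accession labels; runs the t test
    (pooled by default), the two-sided variance-ratio F test and the
    two-sided Mann-Whitney test (exact for small tie-free samples, normal
    approximation with tie correction otherwise).

    Summary mode: pass ``summaries`` mapping trait ->
    (n1, mean1, var1, n2, mean2, var2); Mann-Whitney is unavailable there
    and reported as NaN.
    """
    rows: List[TwoSampleRow] = []
    if summaries is not None:
        for trait, (n1, m1, v1, n2, m2, v2) in summaries.items():
            _, t_p = two_sample_from_summary(n1, m1, v1, n2, m2, v2, equal_var=equal_var)
            _, f_p = variance_ratio_test(n1, v1, n2, v2)
            rows.append(TwoSampleRow(trait, n1, m1, v1, n2, m2, v2, t_p, f_p, np.nan))
        return pd.DataFrame([r.__dict__ for r in rows])

    if table is None or accession_a is None or accession_b is None:
        raise ValueError("raw mode needs table, accession_a and accession_b")
    cols = _trait_columns(table, traits)
    sub_a = table[table[accession_column] == accession_a]
    sub_b = table[table[accession_column] == accession_b]
    if len(sub_a) < 2 or len(sub_b) < 2:
        raise ValueError("each accession needs n >= 2")
    for trait in cols:
        a = pd.to_numeric(sub_a[trait], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(sub_b[trait], errors="coerce").dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append(TwoSampleRow(trait, len(a), np.nan, np.nan, len(b),
                                     np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        v1, v2 = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
        if v1 == 0 and v2 == 0:
            t_p = np.nan
        else:
            _, t_p = two_sample_from_summary(len(a), float(np.mean(a)), v1,
                                             len(b), float(np.mean(b)), v2,
                                             equal_var=equal_var)
        _, f_p = variance_ratio_test(len(a), v1, len(b), v2)
        method = "exact" if (max(len(a), len(b)) <= 8
                             and len(np.unique(np.concatenate([a, b])))
                             == len(a) + len(b)) else "asymptotic"
        _, mw_p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(TwoSampleRow(trait, len(a), float(np.mean(a)), v1,
                                 len(b), float(np.mean(b)), v2,
                                 float(t_p), f_p, float(mw_p)))
    return pd.DataFrame([r.__dict__ for r in rows])
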