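"""Multi-operator comparability statistics.

The comparability question — can gray-scale measurements from different
sonographers and consoles be pooled? — is answered per variable (the GSM
plus the 14 brightness-range percentages, 15 variables in all) with
rank-based nonparametric tests: Anderson-Darling to check (and typically
reject) normality, the Kruskal-Wallis H test across all operators, and
pairwise two-sided Wilcoxon-Mann-Whitney rank-sum tests, all at
significance level 0.05.  No multiple-testing correction is applied; the
protocol reports uncorrected per-variable tests and prints how many tests
were run.

The test statistics are computed in-package (mid-rank ties, tie-corrected
H with a chi-square reference, exact rank-sum null distribution for small
untied samples, normal approximation with tie and continuity corrections
otherwise); scipy supplies only primitives (ranking, distribution tails).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .errors import (
    DegenerateSampleError,
    InsufficientGroupsError,
    ValidationError,
)

ALPHA_DEFAULT = 0.05


# --------------------------------------------------------------------------
# Anderson-Darling normality test (mean and variance estimated)

def anderson_darling_normality(sample: Sequence[float]) -> tuple[float, float]:
    """Anderson-Darling test of composite normality.

    Returns ``(A2, p)`` where A2 carries the small-sample correction
    ``A2* = A2 (1 + 0.75/n + 2.25/n^2)`` and p comes from the standard
    piecewise exponential approximation for the estimated-parameters case.
    Requires n >= 8 and non-zero variance.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise DegenerateSampleError(f"Anderson-Darling needs n >= 8, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateSampleError("sample has zero variance")
    z = norm.cdf((x - x.mean()) / s)
    # Guard exact 0/1 CDF values arising from extreme standardized scores.
    z = np.clip(z, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(a2_star), float(min(max(p, 0.0), 1.0))


# --------------------------------------------------------------------------
# Kruskal-Wallis

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H test (rank ANOVA) over k >= 2 independent groups.

    Mid-ranks for ties, tie-corrected H, chi-square p with k-1 degrees of
    freedom.  If every observation is identical the statistic is defined
    as 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientGroupsError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValidationError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValidationError("Kruskal-Wallis needs at least 3 observations")
    k = len(groups)
    df = k - 1
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0.0:  # all observations identical
        return 0.0, df, 1.0
    h /= denom
    return float(h), df, float(chi2.sf(h, df))


# --------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney rank-sum

@lru_cache(maxsize=64)
def _mann_whitney_null(n1: int, n2: int) -> np.ndarray:
    """Counts of the Mann-Whitney U null distribution for untied samples.

    ``out[u]`` is the number of the C(n1+n2, n1) group assignments with
    U = u; built by the classic recurrence f(n1, n2, u) =
    f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    # dp[j, u] = count for j observations in group 1 out of the first
    # (i + j) pooled ranks; iterate i over group-2 sizes.
    max_u = n1 * n2
    dp = np.zeros((n1 + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        new = dp.copy()
        for j in range(min(i, n1), 0, -1):
            # assigning rank i to group 1 as its j-th member contributes
            # (i - j) pairs to U; paths where that exceeds n1*n2 can never
            # end with exactly n2 group-2 members, so they are dropped
            u_add = i - j
            if u_add > max_u:
                continue
            new[j, u_add:] = dp[j, u_add:] + dp[j - 1, : max_u + 1 - u_add]
        dp = new
    return dp[n1]


def _exact_rank_sum_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p by symmetry of U about n1*n2/2."""
    counts = _mann_whitney_null(n1, n2)
    total = counts.sum()
    center = n1 * n2 / 2.0
    dev = abs(u - center)
    us = np.arange(counts.size)
    p = counts[np.abs(us - center) >= dev - 1e-12].sum() / total
    return float(min(p, 1.0))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test for two independent samples.

    Returns ``(W, p)`` where W is the rank sum of the first sample.  The
    exact null distribution is used when both samples have n <= 25 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both samples need at least one observation")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n1 <= 25 and n2 <= 25 and not has_ties:
        return w, _exact_rank_sum_p(u, n1, n2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return w, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(z)))


# --------------------------------------------------------------------------
# Per-category multi-operator report

GSM_VARIABLE = "gsm"


def band_columns(table: pd.DataFrame) -> list[str]:
    """The brightness-band percentage columns of a results table."""
    return [c for c in table.columns if c.startswith("band_")]


def analysis_variables(table: pd.DataFrame) -> list[str]:
    """GSM plus the brightness-band percentages (15 variables by default)."""
    if GSM_VARIABLE not in table.columns:
        raise ValidationError("results table has no 'gsm' column")
    return [GSM_VARIABLE] + band_columns(table)


@dataclass
class StatReport:
    """Per-variable omnibus and pairwise comparison results for one image
    category.

    ``kruskal`` has one row per variable (H, df, p); ``pairwise`` one row
    per variable x group pair (rank-sum W, p, significant flag);
    ``pair_significant_counts`` one row per group pair with the number of
    brightness bands flagged significant and whether the GSM was flagged.
    """

    category: str
    grouping: str
    alpha: float
    n_tests: int
    kruskal: pd.DataFrame
    pairwise: pd.DataFrame
    pair_significant_counts: pd.DataFrame


def compare_physicians(
    table: pd.DataFrame,
    category: str,
    grouping: str = "physician",
    alpha: float = ALPHA_DEFAULT,
) -> StatReport:
    """Compare operators (or devices) within one image category.

    For each of the 15 analysis variables: a Kruskal-Wallis test across
    all groups, then a pairwise rank-sum test for every group pair
    (pairwise tests run regardless of the omnibus outcome).  Percentages
    are treated as continuous variables.
    """
    if grouping not in ("physician", "device"):
        raise ValidationError("grouping must be 'physician' or 'device'")
    group_col = f"{grouping}_id"
    sub = table[table["category"] == category]
    group_ids = sorted(sub[group_col].unique())
    if len(group_ids) < 2:
        raise InsufficientGroupsError(
            f"category {category!r} has {len(group_ids)} group(s); need >= 2"
        )
    variables = analysis_variables(sub)

    kw_rows = []
    pw_rows = []
    for var in variables:
        groups = [sub.loc[sub[group_col] == g, var].to_numpy() for g in group_ids]
        h, df, p = kruskal_wallis(groups)
        kw_rows.append({"variable": var, "H": h, "df": df, "p": p})
        for (ga, a), (gb, b) in itertools.combinations(zip(group_ids, groups), 2):
            w, pp = wilcoxon_rank_sum(a, b)
            pw_rows.append(
                {
                    "variable": var,
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": w,
                    "p": pp,
                    "significant": bool(pp < alpha),
                }
            )
    kruskal_df = pd.DataFrame(kw_rows)
    pairwise_df = pd.DataFrame(pw_rows)

    count_rows = []
    for (ga, gb), grp in pairwise_df.groupby(["group_a", "group_b"], sort=True):
        bands = grp[grp["variable"] != GSM_VARIABLE]
        gsm_row = grp[grp["variable"] == GSM_VARIABLE]
        count_rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "significant_bands": int(bands["significant"].sum()),
                "gsm_significant": bool(gsm_row["significant"].any()),
            }
        )
    counts_df = pd.DataFrame(count_rows)
    return StatReport(
        category=category,
        grouping=grouping,
        alpha=alpha,
        n_tests=len(kw_rows) + len(pw_rows),
        kruskal=kruskal_df,
        pairwise=pairwise_df,
        pair_significant_counts=counts_df,
    )
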