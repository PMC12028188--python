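"""Univariate statistical screen: Spearman correlations against AFP,
Kruskal-Wallis group comparison with Dunn's post hoc, and an
Anderson-Darling normality gate.

The screen runs on pre-imputation data with pairwise deletion, which is
why each row of the correlation table carries its own sample count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError
from .synthetic import AGE_VARS, BIOCHEMICAL_VARS, VisitRecord, records_to_frame

__all__ = [
    "CorrelationRow",
    "GroupComparison",
    "spearman",
    "association_table",
    "compare_groups",
    "normality_check",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationRow:
    variable: str
    rho: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    h_statistic: float
    p_value: float
    #: Dunn z statistics, groups x groups (antisymmetric)
    z_matrix: np.ndarray
    #: Bonferroni-adjusted two-sided p-values, groups x groups (symmetric)
    p_adjusted: np.ndarray


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float],
             variable: str = "") -> CorrelationRow:
    """Spearman rank correlation with pairwise deletion of missing pairs.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value uses
    the t approximation.
    """
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise DegenerateInputError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(xs, ys)
    return CorrelationRow(variable=variable, rho=float(rho), p_value=float(p), n=n)


def association_table(records: Sequence[VisitRecord],
                      target: str = "afp") -> pd.DataFrame:
    """Correlation screen of every continuous variable against AFP,
    ordered by descending rho."""
    df = records_to_frame(records)
    variables = [v for v in BIOCHEMICAL_VARS + AGE_VARS
                 if v not in (target, "suac_detected")]
    rows = []
    for var in variables:
        row = spearman(df[var], df[target], variable=var)
        rows.append({"variable": row.variable, "rho": row.rho,
                     "p_value": row.p_value, "n": row.n,
                     "significant": row.p_value < ALPHA})
    out = pd.DataFrame(rows).sort_values("rho", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def compare_groups(samples: Sequence[Sequence[float]],
                   alpha: float = ALPHA) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis omnibus test plus Dunn's pairwise
    post hoc z tests with Bonferroni adjustment."""
    groups = [np.asarray(g, dtype=float) for g in samples]
    groups = [g[~np.isnan(g)] for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 1 for g in groups):
        raise InsufficientDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 5:
        raise InsufficientDataError("need >= 5 observations in total")

    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)

    # Dunn's test on mid-ranks of the pooled sample
    ranks = stats.rankdata(pooled)
    sizes = np.array([len(g) for g in groups])
    ends = np.cumsum(sizes)
    starts = ends - sizes
    mean_ranks = np.array([ranks[s:e].mean() for s, e in zip(starts, ends)])
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_corr

    z = np.zeros((k, k))
    p_adj = np.ones((k, k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            praw = 2.0 * stats.norm.sf(abs(zij))
            z[i, j], z[j, i] = zij, -zij
            p_adj[i, j] = p_adj[j, i] = min(1.0, praw * n_pairs)
    return GroupComparison(h_statistic=float(h), p_value=float(p),
                           z_matrix=z, p_adjusted=p_adj)


def normality_check(x: Sequence[float], alpha: float = ALPHA):
    """Anderson-Darling A^2 against the normal family with estimated
    mean/variance.  Returns ``(statistic, passed)``; a failed check means
    downstream comparisons should stay rank-based."""
    xs = np.asarray(x, dtype=float)
    xs = xs[~np.isnan(xs)]
    if len(xs) < 8:
        raise InsufficientDataError(f"normality check needs n >= 8, got {len(xs)}")
    if np.all(xs == xs[0]):
        raise DegenerateInputError("normality check undefined for a constant vector")
    import warnings

    with warnings.catch_warnings():
        # keep the critical-value API; the replacement interpolated-p API
        # changes the return object
        warnings.simplefilter("ignore", FutureWarning)
        result = stats.anderson(xs, dist="norm")
    idx = int(np.argmin(np.abs(result.significance_level - alpha * 100)))
    critical = result.critical_values[idx]
    return float(result.statistic), bool(result.statistic < critical)
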