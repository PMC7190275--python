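"""Association statistics used throughout the study's analyses.

Pearson correlation, Mann-Whitney U (exact by enumeration at small n),
one-way ANOVA with Tukey-Kramer post hoc, and two-way ANOVA with Bonferroni
post hoc.  Test statistics are computed here from first principles; only the
reference distributions (t, F, normal, studentized range) come from
scipy.stats.  All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "pearson",
    "mann_whitney_u",
    "anova_tukey",
    "two_way_anova_bonferroni",
]

EXACT_MWU_MAX_N = 12  # combined sample size up to which the exact null is enumerated


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_two_sided: float


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_two_sided: float
    method: str
    pairwise_adjusted_p: Mapping[tuple, float] = field(default_factory=dict)
    extra: Mapping[str, float] = field(default_factory=dict)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the t-test on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, n, math.copysign(math.inf, r), 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, n, t, min(p, 1.0))


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is min(U_a, U_b), invariant to group order.  With
    ``mode="auto"`` the null is enumerated exactly over all label
    arrangements when the combined n is <= 12 and there are no ties;
    otherwise a tie-corrected normal approximation with continuity
    correction is used.  ``mode`` may force ``"exact"`` or ``"normal"``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_a = _u_from_ranks(ranks[:n_a], n_a)
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    has_ties = np.unique(pooled).size < pooled.size

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and n_a + n_b <= EXACT_MWU_MAX_N and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact enumeration requires tie-free data")

    if use_exact:
        # Enumerate every assignment of n_a labels to the pooled ranks; the
        # null is symmetric around n_a*n_b/2, so two-sided p counts
        # arrangements at least as extreme in |U - mean|.
        mean_u = n_a * n_b / 2.0
        obs_dev = abs(u_a - mean_u)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u_perm = _u_from_ranks(ranks[list(idx)], n_a)
            if abs(u_perm - mean_u) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        return GroupTestResult(u, min(p, 1.0), "mann-whitney-exact")

    n = n_a + n_b
    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:
        return GroupTestResult(u, 1.0, "mann-whitney-normal")
    z = (abs(u_a - mean_u) - 0.5) / math.sqrt(var_u)
    p = 2.0 * float(sps.norm.sf(max(z, 0.0)))
    return GroupTestResult(u, min(p, 1.0), "mann-whitney-normal")


def anova_tukey(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """One-way ANOVA F test plus Tukey's HSD post hoc.

    Unequal group sizes use the Tukey-Kramer standard error; pairwise
    p-values come from the studentized-range distribution with k groups and
    the within-groups degrees of freedom.
    """
    gs = [np.asarray(g, float) for g in groups]
    k = len(gs)
    if k < 3:
        raise ValueError("one-way ANOVA + Tukey here expects >= 3 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, int(ns.sum()) - k
    ms_within = ss_within / df_w
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("F undefined: zero variance within and between groups")
    if ms_within == 0.0:
        f = math.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / ms_within
        p = float(sps.f.sf(f, df_b, df_w))
    pairwise: dict[tuple, float] = {}
    for i, j in itertools.combinations(range(k), 2):
        if ms_within == 0.0:
            pairwise[(i, j)] = 0.0 if means[i] != means[j] else 1.0
            continue
        se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        pairwise[(i, j)] = float(sps.studentized_range.sf(q, k, df_w))
    return GroupTestResult(
        f, min(p, 1.0), "anova-tukey", pairwise,
        {"df_between": df_b, "df_within": df_w, "ms_within": ms_within},
    )


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummy columns (first level as reference)."""
    uniq = np.unique(levels)
    return np.column_stack([(levels == u).astype(float) for u in uniq[1:]])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova_bonferroni(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    posthoc_within: str = "b",
) -> GroupTestResult:
    """Two-factor ANOVA (type-II sums of squares) + Bonferroni post hoc.

    Main effects are tested after the other main effect, the interaction
    after both.  Post hoc: at each level of one factor, pairwise two-sample
    t-tests between the levels of the other factor using the full-model
    residual variance, with p multiplied by the total number of comparisons
    and clamped at 1.  The reported headline statistic/p is the interaction
    F test.
    """
    y = np.asarray(values, float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    la, lb = np.unique(fa), np.unique(fb)
    if la.size < 2 or lb.size < 2:
        raise ValueError("both factors need >= 2 levels")
    cells = {(A, B): y[(fa == A) & (fb == B)] for A in la for B in lb}
    sizes = {k: v.size for k, v in cells.items()}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("incomplete layout: empty factor-level cell")
    if len(set(sizes.values())) > 1:
        warnings.warn(
            "unbalanced two-factor layout; using type-II sums of squares",
            stacklevel=2,
        )

    ones = np.ones((y.size, 1))
    da, db = _dummies(fa), _dummies(fb)
    dab = np.column_stack(
        [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
    )
    rss_a = _rss(np.hstack([ones, da]), y)
    rss_b = _rss(np.hstack([ones, db]), y)
    rss_ab_main = _rss(np.hstack([ones, da, db]), y)
    rss_full = _rss(np.hstack([ones, da, db, dab]), y)

    df_a, df_b = la.size - 1, lb.size - 1
    df_int = df_a * df_b
    df_err = y.size - la.size * lb.size
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom (need replication)")
    mse = rss_full / df_err

    def ftest(ss: float, df: int) -> tuple[float, float]:
        ss = max(ss, 0.0)
        if mse == 0.0:
            return (math.inf, 0.0) if ss > 0 else (0.0, 1.0)
        f = (ss / df) / mse
        return f, float(sps.f.sf(f, df, df_err))

    f_a, p_a = ftest(rss_b - rss_ab_main, df_a)
    f_b, p_b = ftest(rss_a - rss_ab_main, df_b)
    f_i, p_i = ftest(rss_ab_main - rss_full, df_int)

    # Bonferroni post hoc: pairwise t-tests within each level of the
    # stratifying factor, multiplied by the total comparison count.
    if posthoc_within == "b":
        strata, compare = lb, la
        cell = lambda c, s: cells[(c, s)]
    elif posthoc_within == "a":
        strata, compare = la, lb
        cell = lambda c, s: cells[(s, c)]
    else:
        raise ValueError("posthoc_within must be 'a' or 'b'")
    pairs = list(itertools.combinations(compare, 2))
    m = len(pairs) * len(strata)
    pairwise: dict[tuple, float] = {}
    for s in strata:
        for c1, c2 in pairs:
            g1, g2 = cell(c1, s), cell(c2, s)
            if mse == 0.0:
                praw = 0.0 if g1.mean() != g2.mean() else 1.0
            else:
                se = math.sqrt(mse * (1.0 / g1.size + 1.0 / g2.size))
                t = (g1.mean() - g2.mean()) / se
                praw = 2.0 * float(sps.t.sf(abs(t), df_err))
            pairwise[(s, c1, c2)] = min(1.0, praw * m)

    return GroupTestResult(
        f_i, min(p_i, 1.0), "two-way-anova-bonferroni", pairwise,
        {
            "F_a": f_a, "p_a": p_a, "F_b": f_b, "p_b": p_b,
            "F_interaction": f_i, "p_interaction": p_i,
            "df_error": df_err, "mse": mse,
        },
    )
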