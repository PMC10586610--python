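"""Nonparametric group comparisons for the quantification outputs.

Mann-Whitney/Wilcoxon rank-sum (exact by enumeration up to a combined
sample size of 12, tie-corrected normal approximation with continuity
correction above), Kruskal-Wallis with tie correction, and two-sided Dunn
post-hoc z-tests with Bonferroni correction over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = ["TestResult", "mann_whitney", "kruskal_wallis", "dunn_posthoc"]

EXACT_LIMIT = 12


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str  # "exact" | "normal_approx" | "chi2_approx"
    n_per_group: list[int]


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Rank-sum test of two samples; U statistic for the first sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    n1, n2 = x.size, y.size
    n = n1 + n2
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    if n <= EXACT_LIMIT:
        # Permutation distribution of the rank sum over all label splits.
        total = ge = le = 0
        for combo in combinations(range(n), n1):
            s = ranks[list(combo)].sum()
            total += 1
            if s >= r1 - 1e-9:
                ge += 1
            if s <= r1 + 1e-9:
                le += 1
        p_greater, p_less = ge / total, le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return TestResult(u, p, "exact", [n1, n2])

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var == 0:
        return TestResult(u, 1.0, "normal_approx", [n1, n2])
    sd = np.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf((u - mu - 0.5) / sd))
    elif alternative == "less":
        p = float(norm.cdf((u - mu + 0.5) / sd))
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return TestResult(u, max(p, np.finfo(float).tiny), "normal_approx", [n1, n2])


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with midranks, tie correction and chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled, method="average")
    h = 0.0
    start = 0
    for sz in sizes:
        h += ranks[start : start + sz].sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction == 0:  # every observation identical
        return TestResult(0.0, 1.0, "chi2_approx", sizes)
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult(h, max(p, np.finfo(float).tiny), "chi2_approx", sizes)


def dunn_posthoc(groups, correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise Dunn z-tests after a Kruskal-Wallis comparison.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term sum(t^3 - t); two-sided normal p, Bonferroni-scaled
    by the number of pairs.  Returns a table with one row per pair.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Dunn post-hoc needs >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled, method="average")
    means = []
    start = 0
    for sz in sizes:
        means.append(ranks[start : start + sz].mean())
        start += sz
    sigma2 = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        denom = np.sqrt(sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (means[i] - means[j]) / denom
        p_raw = float(min(1.0, 2.0 * norm.sf(abs(z))))
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "n_i": sizes[i],
                "n_j": sizes[j],
                "z": z,
                "p_raw": p_raw,
                "p_corrected": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)
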