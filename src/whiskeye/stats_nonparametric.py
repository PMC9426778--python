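"""Rank-based nonparametric tests used throughout the analyses.

All tests are implemented here rather than delegated so that the exact
small-sample behaviour is under our control and can be validated against
brute-force enumeration oracles.  The U statistic is defined as the number
of (x, y) pairs with x > y, counting ties as 1/2 — so U / (n1*n2) equals
the area under the ROC curve with x as the positive class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .errors import AnalysisError

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "bonferroni",
]

#: total sample size at or below which the Mann-Whitney test enumerates the
#: exact permutation distribution instead of using the normal approximation
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise AnalysisError(f"p_value out of range: {self.p_value}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Number of (x, y) pairs with x > y, ties counted 1/2."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Enumerate every assignment of the pooled sample to the two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    u_obs = _u_statistic(x, y)
    n1n2 = n1 * (n - n1)
    idx = range(n)
    us = []
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    total = len(us)
    eps = 1e-9
    if alternative == "greater":
        p = np.sum(us >= u_obs - eps) / total
    elif alternative == "less":
        p = np.sum(us <= u_obs + eps) / total
    else:
        # two-sided: how extreme is the observed U toward either tail
        extreme_obs = min(u_obs, n1n2 - u_obs)
        extreme = np.minimum(us, n1n2 - us)
        p = np.sum(extreme <= extreme_obs + eps) / total
    return u_obs, min(1.0, float(p))


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Uses exact enumeration of the permutation distribution when the pooled
    sample size is at most :data:`EXACT_ENUMERATION_LIMIT`, otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AnalysisError("mann_whitney_u requires non-empty groups")
    if alternative not in ("two-sided", "greater", "less"):
        raise AnalysisError(f"unknown alternative: {alternative!r}")
    n1, n2 = len(x), len(y)
    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        u, p = _exact_mwu_p(x, y, alternative)
        return TestResult(u, p, f"mann-whitney-u/exact/{alternative}", (n1, n2))
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values identical
        return TestResult(u, 1.0, f"mann-whitney-u/normal/{alternative}", (n1, n2))
    sigma = math.sqrt(sigma2)
    if alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = _sps.norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = _sps.norm.cdf(z)
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p = 2.0 * _sps.norm.sf(z)
    return TestResult(u, min(1.0, float(p)), f"mann-whitney-u/normal/{alternative}", (n1, n2))


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = _sps.rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + len(g)])
        start += len(g)
    return pooled, out


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction and chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise AnalysisError("kruskal_wallis requires >=2 groups")
    if any(len(g) == 0 for g in groups):
        raise AnalysisError("kruskal_wallis requires non-empty groups")
    ns = tuple(len(g) for g in groups)
    n = sum(ns)
    pooled, group_ranks = _pooled_ranks(groups)
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (np.mean(r) - (n + 1) / 2.0) ** 2 for r in group_ranks
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    if tie_corr == 0.0:  # every observation identical: no evidence either way
        return TestResult(0.0, 1.0, "kruskal-wallis", ns)
    h /= tie_corr
    p = float(_sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult(float(h), min(1.0, p), "kruskal-wallis", ns)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction: min(1, m * p).

    ``m`` defaults to the number of p-values supplied.
    """
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if m is None:
        m = len(p)
    if m < 1:
        raise AnalysisError("bonferroni requires m >= 1")
    if np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out[0]) if scalar else out


def dunn_posthoc(groups, correction: str = "bonferroni", reference: int | None = None):
    """Dunn's post hoc pairwise z tests on pooled ranks.

    With ``reference`` set, only the k-1 comparisons against that group are
    performed (and corrected for); otherwise all pairs are compared.
    Returns a dict mapping (i, j) group-index pairs to :class:`TestResult`.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise AnalysisError("dunn_posthoc requires >=2 groups")
    if any(len(g) == 0 for g in groups):
        raise AnalysisError("dunn_posthoc requires non-empty groups")
    if correction not in ("bonferroni", "none"):
        raise AnalysisError(f"unknown correction: {correction!r}")
    pooled, group_ranks = _pooled_ranks(groups)
    n = len(pooled)
    mean_ranks = [np.mean(r) for r in group_ranks]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    if reference is not None:
        pairs = [(reference, j) for j in range(len(groups)) if j != reference]
    else:
        pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    results: dict[tuple[int, int], TestResult] = {}
    for i, j in pairs:
        ni, nj = len(groups[i]), len(groups[j])
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = 2.0 * float(_sps.norm.sf(abs(z)))
        tag = "none"
        if correction == "bonferroni":
            p = bonferroni(min(1.0, p), m)
            tag = f"bonferroni(m={m})"
        results[(i, j)] = TestResult(z, min(1.0, p), "dunn", (ni, nj), correction=tag)
    return results
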