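"""Rank-based nonparametric statistics.

Self-contained implementations of the tests the disconnection-symptom
cascade relies on: tie-averaged ranking, the Kruskal-Wallis H test,
the Mann-Whitney U test (exact by enumeration for small tie-free
samples, normal approximation with tie correction otherwise), the
step-down Holm adjustment, and the Spearman rank correlation.

The exact Mann-Whitney null distribution is computed by the classical
counting recursion, which doubles as an independent oracle for the
test's exact branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import t as _t

__all__ = [
    "TestResult",
    "rank_with_ties",
    "kruskal_wallis",
    "mann_whitney_u",
    "holm_correction",
    "spearman_rho",
    "exact_mwu_null",
]

#: exact Mann-Whitney enumeration is used when n_a * n_b is at most this
#: and the pooled sample is tie-free.
EXACT_MWU_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Outcome of one rank test.

    statistic is H for Kruskal-Wallis, U (of the first group) for
    Mann-Whitney, and rho for Spearman. method records which p-value
    route was taken: "exact", "normal_approx" or "chi2_approx" (or
    "t_approx" for Spearman).
    """

    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def rank_with_ties(values) -> np.ndarray:
    """Ranks 1..n with tied values sharing the average of their rank span."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a nonempty 1-D array")
    if np.any(np.isnan(x)):
        raise ValueError("NaN values cannot be ranked")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        # ranks i+1 .. j+1 (1-based) averaged over the tie run
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled data."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H is tie-corrected; the p-value comes from the chi-square upper tail
    with k-1 degrees of freedom. A fully tied pooled sample (the tie
    correction denominator vanishes) is defined as H = 0, p = 1 so that
    a voxelwise loop never crashes on degenerate clusters.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = np.array([g.size for g in groups])
    big_n = int(pooled.size)
    if big_n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rank_with_ties(pooled)
    # mean rank per group
    h = 0.0
    start = 0
    for ni in n:
        rbar = ranks[start : start + ni].mean()
        h += ni * rbar**2
        start += ni
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (big_n**3 - big_n)
    if denom <= 0.0:
        # every value tied: no rank information at all
        return TestResult(0.0, 1.0, tuple(int(x) for x in n), "chi2_approx")
    h /= denom
    h = max(h, 0.0)
    p = float(_chi2.sf(h, df=len(groups) - 1))
    return TestResult(float(h), min(p, 1.0), tuple(int(x) for x in n), "chi2_approx")


@lru_cache(maxsize=128)
def _mwu_counts(n_a: int, n_b: int) -> np.ndarray:
    """Null counts of U_a by the Mann-Whitney partition recursion.

    f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u), with f(m, 0, u) = [u == 0].
    Counts stay below 2**53 for every (n_a, n_b) the exact branch allows,
    so float64 arithmetic is exact here.
    """
    max_u = n_a * n_b
    prev = np.zeros((n_a + 1, max_u + 1))
    prev[:, 0] = 1.0  # nb = 0
    for nb in range(1, n_b + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for ma in range(1, n_a + 1):
            cur[ma] = prev[ma]
            cur[ma, nb:] += cur[ma - 1, : max_u + 1 - nb]
        prev = cur
    return prev[n_a]


def exact_mwu_null(n_a: int, n_b: int):
    """Exact null probability mass of U_a over 0..n_a*n_b (no ties).

    Returns (u_values, probabilities). Masses sum to 1 and the
    distribution is symmetric about n_a*n_b/2.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    if n_a * n_b > EXACT_MWU_LIMIT:
        raise ValueError(f"n_a*n_b = {n_a * n_b} exceeds exact limit {EXACT_MWU_LIMIT}")
    from math import comb

    counts = _mwu_counts(n_a, n_b)
    total = comb(n_a + n_b, n_a)
    pmf = counts / float(total)
    return np.arange(n_a * n_b + 1), pmf


def mann_whitney_u(a, b, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test; U is reported for the first group a.

    U_a = R_a - n_a(n_a+1)/2 with R_a the sum of a's pooled ranks. The
    p-value is exact (full enumeration of the null U distribution) when
    n_a*n_b <= 400 and the pooled data are tie-free; otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_a, n_b = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = rank_with_ties(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n_a * n_b <= EXACT_MWU_LIMIT:
        _, pmf = exact_mwu_null(n_a, n_b)
        u_int = int(round(u_a))
        cdf_le = float(pmf[: u_int + 1].sum())
        sf_ge = float(pmf[u_int:].sum())
        if alternative == "less":
            p = cdf_le
        elif alternative == "greater":
            p = sf_ge
        else:
            p = min(1.0, 2.0 * min(cdf_le, sf_ge))
        return TestResult(u_a, p, (n_a, n_b), "exact")

    mean = n_a * n_b / 2.0
    big_n = n_a + n_b
    tie = _tie_term(pooled)
    var = n_a * n_b / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        # all values tied: U is exactly its mean, no evidence either way
        return TestResult(u_a, 1.0, (n_a, n_b), "normal_approx")
    sd = np.sqrt(var)
    if alternative == "less":
        z = (u_a - mean + 0.5) / sd
        p = float(_norm.cdf(z))
    elif alternative == "greater":
        z = (u_a - mean - 0.5) / sd
        p = float(_norm.sf(z))
    else:
        z = (abs(u_a - mean) - 0.5) / sd
        p = float(2.0 * _norm.sf(max(z, 0.0)))
    return TestResult(u_a, min(p, 1.0), (n_a, n_b), "normal_approx")


def holm_correction(p_values) -> np.ndarray:
    """Step-down Holm (Bonferroni-Holm) adjusted p-values, original order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce the
    running maximum, cap at 1. Uniformly no more conservative than plain
    Bonferroni.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("need a 1-D list of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        tval = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * _t.sf(abs(tval), df=n - 2))
    return TestResult(rho, min(p, 1.0), (n,), "t_approx")
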