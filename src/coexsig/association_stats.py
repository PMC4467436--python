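"""Inferential statistics for coexpression-subtype association analyses.

Every test here is implemented from its definition rather than delegated to a
statistics library, because reproducing printed p-values requires control over
tail conventions: two-sided binomial and Fisher p-values use the
minimum-likelihood tail definition, and all combinatorics are evaluated in
log space so that overlap p-values far below 1e-100 remain representable.

The tests provided are the ones a marker-coexpression study leans on:

* :func:`wilcoxon_rank_sum` — enrichment-score differences between subtypes,
* :func:`hypergeom_overlap_test` — gene-set overlap significance,
* :func:`binomial_test` — subtype-split symmetry,
* :func:`fisher_exact` — mutation-by-subtype contingency tables,
* :func:`welch_t_test` — expression differences with unequal variances,
* :func:`bh_fdr` — Benjamini–Hochberg multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp, ndtr, stdtr
from scipy.optimize import brentq

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "hypergeom_overlap_test",
    "binomial_test",
    "fisher_exact",
    "welch_t_test",
    "bh_fdr",
]

# relative slack when comparing point probabilities in minimum-likelihood
# two-sided tails; guards against ties lost to floating-point rounding
_REL_TOL = 1e-7


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``effect`` is test-specific: the rank-sum statistic W for the Wilcoxon
    test, the sample odds ratio for Fisher's exact test, the mean difference
    for the Welch t test.  ``extra`` carries secondary quantities such as the
    conditional-MLE odds ratio.
    """

    statistic: float
    p: float
    effect: float
    n: tuple[int, ...]
    method: str
    extra: dict = field(default_factory=dict)


def _check_groups(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not permitted; filter them first")
    return x, y


def _rankdata_average(v: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    The null distribution of the rank sum W of ``x`` is enumerated exactly
    over all C(n, nx) rank assignments when the pooled size is at most 12 and
    there are no ties; larger or tied samples use the normal approximation
    with the tie-corrected variance and a continuity correction.
    """
    x, y = _check_groups(np.asarray(x), np.asarray(y))
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _rankdata_average(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0

    has_ties = np.unique(pooled).size < n
    if n <= 12 and not has_ties:
        # exact: rank sums over every subset of size nx of the integer ranks
        all_ranks = range(1, n + 1)
        total = 0
        extreme = 0
        dev = abs(w - mu)
        for comb in combinations(all_ranks, nx):
            total += 1
            if abs(sum(comb) - mu) >= dev - 1e-12:
                extreme += 1
        p = extreme / total
        method = "wilcoxon-rank-sum-exact"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(w, 1.0, w, (nx, ny), "wilcoxon-rank-sum-normal")
        # continuity correction shrinks the deviation toward the mean
        z = (abs(w - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = 2.0 * (1.0 - ndtr(z))
        method = "wilcoxon-rank-sum-normal"
    return TestResult(w, min(1.0, float(p)), w, (nx, ny), method)


def _log_hypergeom_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeom(N, K, n)."""
    i = np.asarray(i, dtype=float)
    return (
        gammaln(K + 1)
        - gammaln(i + 1)
        - gammaln(K - i + 1)
        + gammaln(N - K + 1)
        - gammaln(n - i + 1)
        - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_overlap_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric overlap p-value, P(X >= k).

    ``k`` observed overlap, ``K`` size of the first set, ``n`` size of the
    second, ``N`` the gene universe.  The tail sum is accumulated in log
    space, so values such as 1e-106 are returned accurately.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer")
    if k > min(K, n) or K > N or n > N:
        raise ValueError("inconsistent counts: need k <= min(K, n) and K, n <= N")
    if k <= 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    return float(min(1.0, math.exp(logsumexp(_log_hypergeom_pmf(i, K, n, N)))))


def _log_binom_pmf(i: np.ndarray, n: int, p0: float) -> np.ndarray:
    i = np.asarray(i, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p0)
        + (n - i) * math.log1p(-p0)
    )


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test (minimum-likelihood tail definition).

    All outcomes whose point probability does not exceed that of ``k`` are
    summed, the convention of R's ``binom.test``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    i = np.arange(0, n + 1)
    logpmf = _log_binom_pmf(i, n, p0)
    cutoff = logpmf[k] + math.log1p(_REL_TOL)
    return float(min(1.0, math.exp(logsumexp(logpmf[logpmf <= cutoff]))))


def _cmle_odds_ratio(a: int, K: int, n: int, N: int) -> float:
    """Conditional maximum-likelihood odds ratio for a 2x2 table.

    Maximises the noncentral hypergeometric likelihood of the observed cell
    ``a`` given the table margins by solving E_psi[A] = a for psi.
    """
    lo, hi = max(0, n - (N - K)), min(K, n)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    support = np.arange(lo, hi + 1)
    base = _log_hypergeom_pmf(support, K, n, N)

    def mean_minus_a(log_psi: float) -> float:
        logw = base + support * log_psi
        logw -= logsumexp(logw)
        return float(np.exp(logw) @ support) - a

    span = 1.0
    while mean_minus_a(-span) > 0 or mean_minus_a(span) < 0:
        span *= 2.0
        if span > 700:  # numerically at the boundary
            return 0.0 if mean_minus_a(0.0) > 0 else math.inf
    return math.exp(brentq(mean_minus_a, -span, span, xtol=1e-12))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    p sums noncentral-free hypergeometric point probabilities not exceeding
    the observed one (minimum-likelihood convention).  The effect is the
    sample odds ratio ``ad/bc``; the conditional-MLE odds ratio (the quantity
    R's ``fisher.test`` estimates) is reported in ``extra['or_cmle']``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.all(t == np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    N = a + b + c + d
    K, n = a + b, a + c  # row-1 and column-1 margins
    nn = (a + b, c + d)

    if K == 0 or n == 0 or K == N or n == N:
        # a zero margin: the table is degenerate, no association measurable
        return TestResult(
            float(a), 1.0, math.nan, nn, "fisher-exact", {"or_cmle": math.nan, "degenerate": True}
        )

    sample_or = math.inf if b * c == 0 else (a * d) / (b * c)
    lo, hi = max(0, n - (N - K)), min(K, n)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, K, n, N)
    obs = logpmf[a - lo]
    p = float(min(1.0, math.exp(logsumexp(logpmf[logpmf <= obs + math.log1p(_REL_TOL)]))))
    or_cmle = _cmle_odds_ratio(a, K, n, N)
    return TestResult(float(a), p, sample_or, nn, "fisher-exact", {"or_cmle": or_cmle})


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t test with Satterthwaite degrees of freedom."""
    x, y = _check_groups(np.asarray(x), np.asarray(y))
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = float(x.mean() - y.mean())
    if vx == 0 and vy == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, 0.0, (nx, ny), "welch-t")
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / nx + vy / ny
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return TestResult(float(t), float(p), diff, (nx, ny), "welch-t", {"df": float(df)})


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values.
    NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    q = pf[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(q[::-1])[::-1])
    qf = np.empty(m)
    qf[order] = q
    out[finite] = qf
    return out
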