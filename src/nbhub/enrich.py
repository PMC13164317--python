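"""Over-representation statistics for protein sets against a gene-set library.

For a query of size n drawn from a universe of size N, a term of size K with
overlap k is scored by the upper hypergeometric tail P(X >= k), computed in
log-space for numerical stability.  Raw p-values are Benjamini-Hochberg
adjusted across all terms of the library.  The reported effect sizes are the
2x2-table odds ratio (with a Haldane-Anscombe 0.5 correction when any cell
is zero) and a combined score

    c = -ln(p) x z,   z = (k - mu) / sigma

where mu and sigma are the hypergeometric mean and standard deviation of the
overlap under the null.  The z standardization of the observed overlap is
this package's definition; enrichment platforms that calibrate z against a
rank-permutation background will produce different combined scores, so p and
adjusted p are the primary comparable quantities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Set

from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .types import GeneSetLibrary, ProteinSet


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent contingency bounds: k={k}, n={n}, K={K}, N={N}"
        )


def _log_binom(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact in log-space."""
    _check_table(k, n, K, N)
    if k == 0:
        return 1.0
    j_max = min(n, K)
    j_min = max(k, n - (N - K))  # below this the pmf is zero
    if j_min > j_max:
        return 0.0
    log_terms = [
        _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
        for j in range(j_min, j_max + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return list(multipletests(p_values, method="fdr_bh")[1])


def odds_ratio(k: int, n: int, K: int, N: int) -> float:
    """2x2-table odds ratio (a=k, b=n-k, c=K-k, d=N-n-K+k).

    A Haldane-Anscombe correction of +0.5 per cell is applied iff any cell
    is zero, keeping the ratio finite at the table's extremes.
    """
    _check_table(k, n, K, N)
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeom_mean_sd(n: int, K: int, N: int) -> tuple:
    mu = n * K / N
    if N <= 1:
        return mu, 0.0
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    return mu, math.sqrt(max(var, 0.0))


def combined_score(p_value: float, k: int, n: int, K: int, N: int) -> float:
    """-ln(p) x z with z the standardized overlap count (0 when sigma = 0)."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p_value must lie in (0, 1], got {p_value}")
    mu, sd = hypergeom_mean_sd(n, K, N)
    z = 0.0 if sd == 0 else (k - mu) / sd
    return -math.log(p_value) * z


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float
    odds_ratio: float
    combined_score: float
    overlap_members: Set[str]


def enrich(
    query: ProteinSet,
    library: GeneSetLibrary,
    top: int | None = 10,
) -> List[EnrichmentResult]:
    """Test the query against every term of the library.

    Query symbols outside the library universe are dropped before testing
    (they contribute to neither n nor N).  BH adjustment runs across *all*
    terms regardless of ``top``; results are ordered by ascending raw p,
    ties broken by term label, and truncated to ``top`` (None = all).
    """
    testable = query.members & library.universe
    if not testable:
        raise ValueError(
            f"no testable genes: query {query.name!r} is disjoint from the "
            f"library universe"
        )
    n, N = len(testable), len(library.universe)
    labels = sorted(library.terms)
    stats = []
    for label in labels:
        members = library.terms[label]
        overlap = testable & members
        k, K = len(overlap), len(members)
        p = hypergeom_tail(k, n, K, N)
        stats.append((label, k, K, p, overlap))
    adjusted = bh_adjust([s[3] for s in stats])
    results = [
        EnrichmentResult(
            term=label,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            adjusted_p=adj,
            odds_ratio=odds_ratio(k, n, K, N),
            combined_score=combined_score(p, k, n, K, N),
            overlap_members=overlap,
        )
        for (label, k, K, p, overlap), adj in zip(stats, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results if top is None else results[:top]
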