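"""eQTL enrichment of a SNP set against a background.

With ``N`` background SNPs of which ``K`` are eQTLs, and a query set of
``n`` SNPs of which ``k`` are eQTLs, the enrichment p-value is the
upper-tail probability :math:`P(X \\ge k)` for :math:`X` hypergeometric
(population ``N``, ``K`` successes, ``n`` draws) -- the one-sided Fisher
tail of the 2x2 overlap table.  Two variants are provided:

* ``method="ease"`` -- the conservative jackknifed tail that replaces the
  observed overlap ``k`` with ``k - 1``;
* ``method="poisson"`` -- the Poisson upper tail at rate
  :math:`\\lambda = nK/N`, the classical approximation for a rare
  annotation drawn many times.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

__all__ = ["EnrichmentCounts", "enrichment_test", "overlap_counts"]


@dataclass
class EnrichmentCounts:
    """Overlap counts of a query SNP set with an eQTL annotation."""

    N: int  # background size
    K: int  # eQTLs in background
    n: int  # query size
    k: int  # eQTLs in query
    p_enrich: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("background must be non-empty")
        if not (0 <= self.K <= self.N):
            raise ValueError(f"need 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"impossible overlap k={self.k} for K={self.K}, n={self.n}"
            )

    @property
    def fraction_background(self) -> float:
        return self.K / self.N

    @property
    def fraction_query(self) -> float:
        return self.k / self.n if self.n else 0.0

    def summary(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "pct_background": round(100 * self.fraction_background, 1),
            "pct_query": round(100 * self.fraction_query, 1),
            "p_enrich": self.p_enrich,
            "method": self.method,
        }


def enrichment_test(N: int, K: int, n: int, k: int,
                    method: str = "hypergeometric") -> EnrichmentCounts:
    """Upper-tail eQTL enrichment test on overlap counts.

    ``method`` selects the tail: exact hypergeometric ``P(X >= k)`` (default;
    computed by :func:`scipy.stats.hypergeom.sf`, exact summation in
    log-stable form), the EASE jackknife (``k`` replaced by ``k - 1``), or
    the Poisson approximation at rate ``n*K/N``.
    """
    counts = EnrichmentCounts(N=N, K=K, n=n, k=k)
    if method == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif method == "ease":
        p = 1.0 if k < 1 else float(stats.hypergeom.sf(k - 2, N, K, n))
    elif method == "poisson":
        p = float(stats.poisson.sf(k - 1, n * K / N))
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    counts.p_enrich = min(p, 1.0)
    counts.method = method
    return counts


def overlap_counts(
    query: set[str],
    background: set[str],
    eqtl_flags: set[str],
) -> EnrichmentCounts:
    """Overlap counts by set intersection (no p-value attached).

    Query SNPs outside the background are dropped with a warning; eQTL
    membership is evaluated within the background.
    """
    if not background:
        raise ValueError("background SNP set is empty")
    query = set(query)
    background = set(background)
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query SNPs outside the background were dropped",
            stacklevel=2,
        )
        query = query & background
    flags = set(eqtl_flags) & background
    return EnrichmentCounts(
        N=len(background),
        K=len(flags),
        n=len(query),
        k=len(query & flags),
    )
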