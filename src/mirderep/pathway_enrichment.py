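"""Hypergeometric over-representation analysis with BH FDR control.

For a query gene set of effective size n drawn from a universe of N genes,
a pathway with K universe members, and an observed overlap k, the
enrichment p-value is the upper tail

    P(X >= k),   X ~ Hypergeometric(N, K, n)

computed in log-space (lgamma combinatorics, logsumexp over the tail) so
the result is accurate at any parameter scale. One-sided upper tail only:
the question is over-representation. The BH family is the set of pathways
tested for one query, mirroring one enrichment submission per miRNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import norm_symbol

log = logging.getLogger(__name__)


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Parameters follow the sampling description: ``N`` universe size, ``K``
    pathway (success-state) size, ``n`` query (draw) size, ``k`` observed
    overlap. Computed with log-space combinatorics; relative error is at
    the level of float rounding (<= 1e-12 against exact rational
    enumeration over small parameter grids).
    """
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n)={min(K, n)}, got k={k}")
    if k == 0:
        return 1.0
    log_denom = _lchoose(N, n)
    # support of X is [max(0, n-(N-K)), min(K, n)]; terms below it are zero
    lo = max(k, n - (N - K))
    terms = [
        _lchoose(K, i) + _lchoose(N - K, n - i) - log_denom
        for i in range(lo, min(K, n) + 1)
    ]
    if not terms:
        return 0.0
    top = max(terms)
    tail = math.exp(top) * math.fsum(math.exp(t - top) for t in terms)
    return min(tail, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p-values,
    clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation statistics for one query set."""

    query_id: str
    pathway_id: str
    pathway_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    overlap: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError("overlap count out of range")
        if len(self.overlap) != self.k:
            raise ValueError("overlap list length must equal k")
        if not (0.0 < self.p <= 1.0 and self.p <= self.q <= 1.0):
            raise ValueError("require 0 < p <= q <= 1")


def enrich(
    query: Iterable[str],
    collection: "io_formats.PathwayCollection",  # noqa: F821 — forward ref
    universe: Iterable[str],
    query_id: str = "query",
) -> list[EnrichmentResult]:
    """Test every pathway with >= 1 universe member against one query set.

    Query genes and pathway members are intersected with the universe
    first; query genes outside the universe are dropped and counted in the
    log. BH adjustment is across all pathways tested for this query.
    """
    universe_norm = {norm_symbol(g) for g in universe}
    if not universe_norm:
        raise ValueError("universe must be non-empty")
    query_map = {norm_symbol(g): g for g in query}
    dropped = len(query_map.keys() - universe_norm)
    if dropped:
        log.info("query %s: %d genes outside universe dropped", query_id, dropped)
    query_norm = set(query_map) & universe_norm
    N = len(universe_norm)
    n = len(query_norm)
    if n == 0:
        log.warning("query %s is empty after universe intersection", query_id)
        return []

    rows = []
    for pid in sorted(collection.pathways):
        pw = collection.pathways[pid]
        members_norm = {norm_symbol(g) for g in pw.members} & universe_norm
        K = len(members_norm)
        if K == 0:
            continue
        overlap_norm = sorted(query_norm & members_norm)
        k = len(overlap_norm)
        p = hypergeom_upper_tail(k, K, n, N)
        overlap = tuple(query_map[g] for g in overlap_norm)
        rows.append((pid, pw.name, k, K, p, overlap))
    qvals = bh_adjust([r[4] for r in rows])
    return [
        EnrichmentResult(
            query_id=query_id, pathway_id=pid, pathway_name=name,
            k=k, K=K, n=n, N=N, p=p, q=max(q, p), overlap=overlap,
        )
        for (pid, name, k, K, p, overlap), q in zip(rows, qvals)
    ]


def top_pathways(results: Sequence[EnrichmentResult], n: int = 10) -> list[EnrichmentResult]:
    """First ``n`` results sorted by (q asc, p asc, pathway id asc); deterministic under ties."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(results, key=lambda r: (r.q, r.p, r.pathway_id))[:n]


@dataclass(frozen=True)
class SharedPathwayRecord:
    pathway_id: str
    mirnas: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.mirnas)


def significant_pathways(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> set[str]:
    """Pathway ids with BH q below ``alpha`` in one query's results."""
    return {r.pathway_id for r in results if r.q < alpha}


def shared_pathways(
    per_query: Mapping[str, Iterable[str]],
    min_queries: int = 3,
) -> list[SharedPathwayRecord]:
    """Pathways significant for at least ``min_queries`` queries (miRNAs).

    ``per_query`` maps each miRNA to its set of significant pathway ids.
    Sorted by count descending, then pathway id.
    """
    if min_queries < 2:
        raise ValueError("min_queries must be >= 2")
    hits: dict[str, set[str]] = {}
    for mirna, pids in per_query.items():
        for pid in pids:
            hits.setdefault(pid, set()).add(mirna)
    records = [
        SharedPathwayRecord(pathway_id=pid, mirnas=tuple(sorted(ms)))
        for pid, ms in hits.items()
        if len(ms) >= min_queries
    ]
    return sorted(records, key=lambda r: (-r.count, r.pathway_id))
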