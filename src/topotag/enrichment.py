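"""Over-representation analysis of TAG clusters against GMT gene sets.

For a query of n genes drawn from a universe of N genes, a term with K
members in the universe and k of them in the query gets the upper-tail
hypergeometric probability P(X >= k).  P-values are Holm step-down
adjusted within each cluster's term family and called significant at
``alpha`` (default 0.05).

The universe is the caller's choice; the pipeline uses all genes passing
the zero-fraction filter (before the top-150 truncation), the least biased
locally available background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "hypergeom_test",
    "holm_adjust",
    "enrich_clusters",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term tested against one query gene set."""

    term_id: str
    overlap: int        # k
    query_size: int     # n
    term_size: int      # K, after intersecting with the universe
    universe_size: int  # N
    p_value: float
    p_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.term_size):
            raise ValueError("overlap exceeds query or term size")
        if not self.p_adjusted >= self.p_value - 1e-15:
            raise ValueError("adjusted p below raw p")


def hypergeom_test(query: set[str], term_genes: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of the overlap
    between ``query`` and ``term_genes`` within ``universe``.

    The term is intersected with the universe first; the query must be a
    subset of the universe.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    K = len(set(term_genes) & set(universe))
    n = len(set(query))
    k = len(set(query) & set(term_genes))
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    With p-values sorted ascending, adj(i) = min(1, max_{j<=i}
    (m - j + 1) * p_(j)) for 1-based j; monotone and never below the raw
    p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def enrich_clusters(
    tag_sets: dict[int, set[str]],
    gmt: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> dict[int, list[EnrichmentResult]]:
    """Test every GMT term against every TAG cluster.

    Holm adjustment is applied within each cluster's term family;
    results are sorted ascending by adjusted then raw p-value.  Clusters
    with no genes in the universe are skipped with a warning.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    universe = set(universe)
    results: dict[int, list[EnrichmentResult]] = {}
    for cluster_id, genes in tag_sets.items():
        query = set(genes) & universe
        if not query:
            log.warning("cluster %s has no genes in the universe; skipped", cluster_id)
            continue
        term_ids = list(gmt)
        raw = np.array([
            hypergeom_test(query, gmt[t], universe) for t in term_ids
        ])
        adjusted = holm_adjust(raw)
        rows = [
            EnrichmentResult(
                term_id=t,
                overlap=len(query & (gmt[t] & universe)),
                query_size=len(query),
                term_size=len(gmt[t] & universe),
                universe_size=len(universe),
                p_value=float(pr),
                p_adjusted=float(pa),
                significant=bool(pa <= alpha),
            )
            for t, pr, pa in zip(term_ids, raw, adjusted)
        ]
        rows.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term_id))
        results[cluster_id] = rows
    return results
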