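"""Over-representation analysis with the hypergeometric test and BH control."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneSetLibrary

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_genes: list[str]
    k: int  # overlap count
    set_size: int  # set size restricted to the universe
    query_size: int  # query size restricted to the universe
    universe_size: int
    p: float
    p_bh: float


def hypergeom_tail(k: int, set_size: int, query_size: int, universe_size: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe_size, set_size, query_size).

    The probability of drawing at least ``k`` set members in ``query_size``
    draws without replacement; identical to the one-sided Fisher exact test
    on the corresponding 2x2 table.
    """
    if max(set_size, query_size) > universe_size or not (
        0 <= k <= min(set_size, query_size)
    ):
        raise ValueError(
            f"inconsistent counts: k={k}, set={set_size}, "
            f"query={query_size}, universe={universe_size}"
        )
    return float(stats.hypergeom.sf(k - 1, universe_size, set_size, query_size))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adjusted_(i) = min over j >= i of (n * p_(j) / j), capped at 1, where
    p_(1) <= ... <= p_(n). Entries outside (0, 1] raise ``ValueError``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("bh_adjust requires p-values in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


def enrich(
    query: Sequence[str],
    library: GeneSetLibrary,
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` against every library set.

    Gene names are compared case-insensitively. Sets are restricted to the
    universe (sets with no universe member are skipped); query genes not in
    the universe are dropped with a warning. BH adjustment spans all tested
    sets; results are sorted by raw p-value.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("enrichment universe must be non-empty")
    query_set = {g.upper() for g in query}
    outside = query_set - universe_set
    if outside:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(outside), sorted(outside)[:5],
        )
        query_set &= universe_set
    if not query_set:
        logger.warning("empty query after universe restriction; no enrichment computed")
        return []

    results: list[EnrichmentResult] = []
    for name, genes in library.sets.items():
        set_in_universe = {g for g in genes if g in universe_set}
        if not set_in_universe:
            continue
        overlap = sorted(query_set & set_in_universe)
        p = hypergeom_tail(
            len(overlap), len(set_in_universe), len(query_set), len(universe_set)
        )
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_genes=overlap,
                k=len(overlap),
                set_size=len(set_in_universe),
                query_size=len(query_set),
                universe_size=len(universe_set),
                p=p,
                p_bh=np.nan,
            )
        )
    if results:
        adjusted = bh_adjust([r.p for r in results])
        for r, q in zip(results, adjusted):
            r.p_bh = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
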