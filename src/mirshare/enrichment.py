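"""Hypergeometric over-representation analysis with BH correction.

For a query gene set of size n and a library term of size K drawn from a
background of N genes, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution, where k is the observed
overlap — equivalent to the one-sided Fisher exact test.  P-values are
adjusted per library with the Benjamini–Hochberg step-up procedure and
terms are ranked by ascending adjusted p (ties: raw p, then term name).
Only over-representation is tested; depletion is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_GENOME_SIZE

logger = logging.getLogger("mirshare.enrichment")


@dataclass
class EnrichmentQuery:
    """A query gene set tested against one term library."""

    query_genes: frozenset[str]
    library: dict[str, frozenset[str]]
    background_size: int = DEFAULT_GENOME_SIZE


@dataclass
class EnrichmentResult:
    """Term-level hypergeometric statistics with BH-adjusted p and rank."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float = 1.0
    overlap_genes: list[str] = field(default_factory=list)
    rank: int = 0


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exactly 1 when k = 0."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: EnrichmentQuery | None = None,
    top_k: int = 5,
    alpha: float = 0.05,
    *,
    query_genes: Iterable[str] | None = None,
    library: Mapping[str, Iterable[str]] | None = None,
    background_size: int | None = None,
) -> list[EnrichmentResult]:
    """Test every library term, adjust within the library, report the top hits.

    Every term is tested and BH-adjusted as one family; ranks 1..T are
    assigned over all terms by ascending (p_adj, p, term); the returned list
    is restricted to terms with p_adj < ``alpha`` and truncated to the
    ``top_k`` best ranks.
    """
    if query is None:
        query = EnrichmentQuery(
            query_genes=frozenset(query_genes or ()),
            library={t: frozenset(g) for t, g in (library or {}).items()},
            background_size=background_size or DEFAULT_GENOME_SIZE,
        )
    if not query.library:
        raise ValueError("library must be non-empty")
    if not query.query_genes:
        raise ValueError("query gene set is empty")
    n = len(query.query_genes)
    N = query.background_size
    if n > N:
        raise ValueError(f"query size {n} exceeds background size {N}")
    results = []
    for term in sorted(query.library):
        members = query.library[term]
        if len(members) > N:
            raise ValueError(f"term {term!r} larger than the background ({len(members)} > {N})")
        overlap = sorted(query.query_genes & members)
        k = len(overlap)
        results.append(
            EnrichmentResult(
                term=term,
                k=k,
                K=len(members),
                n=n,
                N=N,
                p=hypergeom_upper_tail(k, len(members), n, N),
                overlap_genes=overlap,
            )
        )
    adjusted = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adjusted):
        r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    hits = [r for r in results if r.p_adj < alpha][:top_k]
    logger.info(
        "enrich: %d terms tested, %d significant at p_adj<%s, reporting %d",
        len(results), sum(r.p_adj < alpha for r in results), alpha, len(hits),
    )
    return hits


def shared_target_enrichment(
    targets_A: Iterable[str],
    targets_B: Iterable[str],
    libraries: Mapping[str, Mapping[str, Iterable[str]]],
    background_size: int = DEFAULT_GENOME_SIZE,
    top_k: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of the intersection of two miRNAs' target sets, per library."""
    targets_A, targets_B = set(targets_A), set(targets_B)
    if not targets_A or not targets_B:
        raise ValueError("both target sets must be non-empty")
    common = targets_A & targets_B
    if not common:
        warnings.warn("target sets are disjoint; no common genes to enrich", stacklevel=2)
        return results_to_frame([], library_name=None)
    frames = []
    for name, lib in libraries.items():
        hits = enrich(
            query_genes=common, library=lib,
            background_size=background_size, top_k=top_k, alpha=alpha,
        )
        frames.append(results_to_frame(hits, library_name=name))
    return pd.concat(frames, ignore_index=True) if frames else results_to_frame([], None)


def results_to_frame(
    results: Sequence[EnrichmentResult], library_name: str | None
) -> pd.DataFrame:
    rows = [
        {
            "library": library_name,
            "term": r.term,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "p_adj": r.p_adj,
            "rank": r.rank,
            "overlap_genes": "|".join(r.overlap_genes),
        }
        for r in results
    ]
    columns = ["library", "term", "k", "K", "n", "N", "p", "p_adj", "rank", "overlap_genes"]
    return pd.DataFrame(rows, columns=columns)


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def dotplot_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Dot-plot style summary: term, gene count on the left, rank on the right."""
    return frame[["library", "term", "k", "rank", "p_adj"]].rename(
        columns={"k": "gene_count"}
    )
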