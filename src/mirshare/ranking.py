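"""Multi-source miRNA target aggregation, counting, ranking and clustering.

Predictions from several source databases are collapsed to distinct
(miRNA, gene) pairs with a per-pair source count; per-miRNA target counts
are then taken against the shared gene set and against each full disease
gene universe.  miRNAs are ranked by their shared-target count (ties broken
by the disease-universe counts, then id), the top decile is selected for
prioritization, targets are annotated against named pathway gene lists,
and the ranking is discretized into four ordered clusters by
equal-frequency binning of the shared count (OneR-style, ties kept in one
cluster).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirshare.ranking")

#: Published shared/glioblastoma/Parkinson target counts for the 14
#: candidate miRNAs used in the worked ranking example.
PUBLISHED_RANKING_COUNTS: tuple[tuple[str, int, int, int], ...] = (
    ("hsa-miR-16-5p", 483, 1588, 1014),
    ("hsa-miR-548c-3p", 414, 1424, 882),
    ("hsa-miR-124-3p", 449, 1590, 949),
    ("hsa-miR-1-3p", 470, 1604, 1027),
    ("hsa-miR-34a-5p", 415, 1364, 821),
    ("hsa-miR-155-5p", 422, 1331, 841),
    ("hsa-miR-27a-3p", 408, 1376, 868),
    ("hsa-miR-107", 369, 1240, 760),
    ("hsa-let-7b-5p", 379, 1295, 770),
    ("hsa-miR-590-3p", 375, 1259, 800),
    ("hsa-miR-23b-3p", 365, 1143, 737),
    ("hsa-miR-3163", 353, 1231, 758),
    ("hsa-miR-374a-5p", 338, 1126, 669),
    ("hsa-miR-186-5p", 358, 1211, 745),
)


@dataclass(frozen=True)
class MirnaTargetInteraction:
    """A single predicted miRNA→gene interaction from one source database."""

    mirna_id: str
    gene_id: str
    source_db: str
    score: float | None = None


@dataclass
class MirnaRankRecord:
    """Per-miRNA target counts, pathway annotations, cluster and rank."""

    mirna_id: str
    n_shared: int
    n_B: int
    n_A: int
    n_sources_median: float = 0.0
    pathway_hits: dict[str, list[str]] = field(default_factory=dict)
    cluster: int = 0
    rank: int = 0


def aggregate_predictions(
    interactions: pd.DataFrame | Iterable[MirnaTargetInteraction],
    min_sources: int = 1,
    gene_column: str = "gene_symbol",
) -> pd.DataFrame:
    """Collapse multi-source predictions to distinct pairs with source counts.

    A pair is kept iff it is reported by at least ``min_sources`` distinct
    source databases; with the default of 1 this is the pure union across
    sources.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    if not isinstance(interactions, pd.DataFrame):
        interactions = pd.DataFrame(
            [(i.mirna_id, i.gene_id, i.source_db) for i in interactions],
            columns=["mirna_id", gene_column, "source_db"],
        )
    grouped = (
        interactions.groupby(["mirna_id", gene_column], sort=True)["source_db"]
        .nunique()
        .rename("n_sources")
        .reset_index()
    )
    kept = grouped[grouped["n_sources"] >= min_sources].reset_index(drop=True)
    logger.info(
        "aggregate_predictions: %d pairs -> %d at min_sources=%d",
        len(grouped), len(kept), min_sources,
    )
    return kept


def targets_by_mirna(pairs: pd.DataFrame, gene_column: str = "gene_symbol") -> dict[str, set[str]]:
    return {m: set(g) for m, g in pairs.groupby("mirna_id")[gene_column]}


def count_targets(
    pairs: pd.DataFrame,
    gene_set: Iterable[str],
    gene_column: str = "gene_symbol",
) -> pd.Series:
    """Per-miRNA count of distinct targets falling inside ``gene_set``."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    in_set = pairs[pairs[gene_column].isin(gene_set)]
    counts = in_set.groupby("mirna_id")[gene_column].nunique()
    return counts.reindex(pairs["mirna_id"].unique(), fill_value=0).astype(int)


def build_rank_table(
    pairs: pd.DataFrame,
    shared_genes: Iterable[str],
    universe_B: Iterable[str],
    universe_A: Iterable[str],
    gene_column: str = "gene_symbol",
) -> pd.DataFrame:
    """Count shared/disease-universe targets per miRNA (unranked)."""
    table = pd.DataFrame(
        {
            "n_shared": count_targets(pairs, shared_genes, gene_column),
            "n_B": count_targets(pairs, universe_B, gene_column),
            "n_A": count_targets(pairs, universe_A, gene_column),
            "n_sources_median": pairs.groupby("mirna_id")["n_sources"].median(),
        }
    )
    return table.rename_axis("mirna_id").reset_index()


def rank_mirnas(records: pd.DataFrame) -> pd.DataFrame:
    """Rank descending by shared-target count.

    Ties are broken by the glioblastoma-universe count (descending), then
    the Parkinson-universe count (descending), then miRNA id (ascending);
    ranks are 1..M and unique.
    """
    if records.empty:
        raise ValueError("cannot rank an empty record table")
    ranked = records.sort_values(
        ["n_shared", "n_B", "n_A", "mirna_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def select_top_decile(ranked: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """First ceil(fraction * M) records of a ranked table."""
    if ranked.empty:
        raise ValueError("ranked table is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = math.ceil(fraction * len(ranked))
    return ranked.head(n).reset_index(drop=True)


def annotate_pathways(
    mirna_targets: Iterable[str],
    pathway_lists: Mapping[str, Iterable[str]],
) -> dict[str, list[str]]:
    """Sorted intersection of a miRNA's targets with each named pathway list."""
    if not pathway_lists:
        raise ValueError("pathway_lists must be non-empty")
    targets = set(mirna_targets)
    return {
        name: sorted(targets & set(genes)) for name, genes in pathway_lists.items()
    }


def oner_cluster(ranked: pd.DataFrame, n_clusters: int = 4) -> pd.DataFrame:
    """Ordered equal-frequency binning of the shared-target count.

    Cluster 1 holds the highest counts.  Bin boundaries never split ties:
    a run of equal counts straddling a nominal boundary stays in the earlier
    cluster, so later clusters may be empty (logged when that happens).
    The shared count is non-increasing across cluster boundaries.
    """
    m = len(ranked)
    if m < n_clusters:
        raise ValueError(f"need at least {n_clusters} records, got {m}")
    values = ranked["n_shared"].to_numpy()
    if np.any(np.diff(values) > 0):
        raise ValueError("records must be sorted by descending n_shared (rank first)")
    sizes = [len(chunk) for chunk in np.array_split(np.arange(m), n_clusters)]
    boundaries = np.cumsum(sizes)
    labels = np.zeros(m, dtype=int)
    i = 0
    for cluster, b in enumerate(boundaries, start=1):
        if i >= m:
            break
        if b <= i:
            continue  # swallowed by a tie run; this cluster stays empty
        end = int(b)
        while end < m and values[end] == values[end - 1]:
            end += 1
        labels[i:end] = cluster
        i = end
    out = ranked.copy()
    out["cluster"] = labels
    occupied = sorted(set(labels))
    if len(occupied) < n_clusters:
        logger.info(
            "oner_cluster: only %d of %d clusters occupied (tie runs): %s",
            len(occupied), n_clusters, occupied,
        )
    return out


def published_counts_table() -> pd.DataFrame:
    """The worked-example count table as an unranked record table."""
    return pd.DataFrame(
        PUBLISHED_RANKING_COUNTS, columns=["mirna_id", "n_shared", "n_B", "n_A"]
    )


def write_ranking(
    ranked: pd.DataFrame,
    path: str | Path,
    pathway_hits: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> None:
    """Ranking TSV mirroring the published table layout.

    Pathway columns hold "|"-joined sorted target symbols per pathway.
    """
    out = ranked.copy()
    if pathway_hits:
        pathway_names = sorted({p for hits in pathway_hits.values() for p in hits})
        for name in pathway_names:
            out[name] = [
                "|".join(pathway_hits.get(m, {}).get(name, []))
                for m in out["mirna_id"]
            ]
    out.to_csv(path, sep="\t", index=False)
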