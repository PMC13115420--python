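"""Per-disease gene sets from association tables and shared/exclusive sets.

A disease gene set is the union of genes over the disease's term list after
provenance filtering (source class allowlist, minimum association score).
Shared genes between two diseases are the intersection of the two unions;
the exclusive sets are the set differences.  Gene ids are the primary
identifier namespace — symbols are unstable and kept as annotation only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import FormatError

logger = logging.getLogger("mirshare.gene_sets")

REQUIRED_COLUMNS = (
    "gene_id", "gene_symbol", "term_id", "disease_label", "source_class", "score",
)
DEFAULT_SOURCE_CLASSES = ("curated", "literature")


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """One gene–disease-term association with provenance."""

    gene_id: str
    gene_symbol: str
    term_id: str
    disease_label: str
    source_class: str
    score: float


@dataclass
class DiseaseGeneSet:
    """Union of genes over a disease's term list, after filters."""

    disease_label: str
    term_ids: list[str]
    genes: frozenset[str]
    symbols: frozenset[str] = frozenset()
    provenance_filter: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class SharedGeneSets:
    """Disjoint partition of two disease gene sets: A∩B, A∖B, B∖A."""

    shared: frozenset[str]
    A_only: frozenset[str]
    B_only: frozenset[str]

    def __post_init__(self) -> None:
        if self.shared & self.A_only or self.shared & self.B_only or self.A_only & self.B_only:
            raise ValueError("shared/A_only/B_only must be pairwise disjoint")

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.A_only) + len(self.B_only)


def read_associations(
    path: str | Path,
    source_classes: Sequence[str] = DEFAULT_SOURCE_CLASSES,
    min_score: float = 0.0,
) -> list[GeneDiseaseAssociation]:
    """Read an association TSV, filter by provenance, and deduplicate.

    Rows whose source class is not in the allowlist, or whose score is below
    ``min_score``, are dropped.  Duplicate (gene, term) rows are collapsed
    keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "gene_symbol": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"association file {path} missing required column(s): {', '.join(missing)}"
        )
    n_raw = len(df)
    df = df[df["source_class"].isin(source_classes) & (df["score"] >= min_score)]
    df = (
        df.sort_values("score", kind="mergesort")
        .drop_duplicates(subset=["gene_id", "term_id"], keep="last")
        .sort_values(["disease_label", "term_id", "gene_id"], kind="mergesort")
    )
    logger.info(
        "read_associations: %d raw rows -> %d after filters %s/min_score=%s",
        n_raw, len(df), list(source_classes), min_score,
    )
    if df.empty:
        warnings.warn(f"no associations left after filtering {path}", stacklevel=2)
        return []
    return [
        GeneDiseaseAssociation(
            str(r.gene_id), str(r.gene_symbol), str(r.term_id),
            str(r.disease_label), str(r.source_class), float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def build_disease_set(
    assocs: Iterable[GeneDiseaseAssociation],
    term_ids: Sequence[str],
    disease_label: str | None = None,
    provenance_filter: dict | None = None,
) -> DiseaseGeneSet:
    """Union of gene ids over the requested terms only."""
    term_ids = list(term_ids)
    if not term_ids:
        raise ValueError("term_ids must be non-empty")
    wanted = set(term_ids)
    genes: set[str] = set()
    symbols: set[str] = set()
    seen_terms: set[str] = set()
    label = disease_label
    for a in assocs:
        if a.term_id not in wanted:
            continue
        if disease_label is not None and a.disease_label != disease_label:
            continue
        seen_terms.add(a.term_id)
        genes.add(a.gene_id)
        symbols.add(a.gene_symbol)
        label = label or a.disease_label
    unknown = sorted(wanted - seen_terms)
    if unknown:
        if len(unknown) == len(term_ids):
            raise ValueError(f"none of the requested terms found: {unknown}")
        warnings.warn(f"unknown term_id(s) ignored: {unknown}", stacklevel=2)
    return DiseaseGeneSet(
        disease_label=label or "",
        term_ids=sorted(wanted),
        genes=frozenset(genes),
        symbols=frozenset(symbols),
        provenance_filter=dict(provenance_filter or {}),
    )


def terms_for_disease(
    assocs: Iterable[GeneDiseaseAssociation], disease_label: str
) -> list[str]:
    return sorted({a.term_id for a in assocs if a.disease_label == disease_label})


def intersect(A: DiseaseGeneSet, B: DiseaseGeneSet) -> SharedGeneSets:
    """Shared and exclusive gene sets of two diseases."""
    if not A.genes or not B.genes:
        raise ValueError("cannot intersect an empty disease gene set")
    shared = A.genes & B.genes
    result = SharedGeneSets(
        shared=frozenset(shared),
        A_only=frozenset(A.genes - B.genes),
        B_only=frozenset(B.genes - A.genes),
    )
    logger.info(
        "intersect: |%s|=%d |%s|=%d shared=%d A_only=%d B_only=%d",
        A.disease_label, len(A), B.disease_label, len(B),
        len(result.shared), len(result.A_only), len(result.B_only),
    )
    return result


def write_gene_set(gene_set: DiseaseGeneSet, path: str | Path) -> None:
    """One gene per line (lexicographic) plus a JSON summary side file."""
    path = Path(path)
    path.write_text("\n".join(gene_set.sorted_genes()) + "\n")
    summary = {
        "disease": gene_set.disease_label,
        "n_terms": len(gene_set.term_ids),
        "n_genes": len(gene_set),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )


def read_gene_set(path: str | Path, disease_label: str = "") -> DiseaseGeneSet:
    genes = [g for g in Path(path).read_text().splitlines() if g]
    return DiseaseGeneSet(disease_label=disease_label, term_ids=[], genes=frozenset(genes))
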