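"""Synthetic input generators with planted ground truth.

Every input the pipeline consumes can be generated here, emulating the
upstream resources the analysis would normally query:

* gene–disease association tables (DisGeNET-style TSV),
* multi-source miRNA→target prediction tables (multimiR-style TSV),
* gene-set libraries (GMT, Enrichr-style),
* scored interactome edge lists (STRING-style TSV),
* RT-qPCR Ct tables and ELISA concentration tables (CSV).

The generators plant recoverable structure — an exact disease-set overlap,
miRNAs with a high shared-target rate, enriched terms, network hubs, and
log2 expression effects — so every downstream stage can be tested against
known truth without any download.

Determinism: each generator draws from its own RNG stream, seeded from
``config.seed`` plus a stable per-generator offset, so identical
config+seed gives byte-identical outputs and adding a generator never
perturbs another generator's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    CT_UNDETECTABLE,
    ConfigurationError,
    SimulationConfig,
    config_to_dict,
)

logger = logging.getLogger("mirshare.synthetic")

SOURCE_CLASSES = ("curated", "literature")


# ---------------------------------------------------------------------------
# gene universe and planted disease partition
# ---------------------------------------------------------------------------

def gene_universe(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene universe: stable ids and 1:1 symbols."""
    idx = np.arange(config.n_genes_universe)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in idx],
            "gene_symbol": [f"GENE{i:05d}" for i in idx],
        }
    )


def _partition_indices(config: SimulationConfig, rng: np.random.Generator):
    """Draw the planted partition: overlap is planted exactly, not sampled."""
    perm = rng.permutation(config.n_genes_universe)
    n_shared = config.overlap_size
    n_a_only = config.disease_A_size - n_shared
    n_b_only = config.disease_B_size - n_shared
    shared = perm[:n_shared]
    a_only = perm[n_shared : n_shared + n_a_only]
    b_only = perm[n_shared + n_a_only : n_shared + n_a_only + n_b_only]
    return shared, a_only, b_only


def planted_partition(config: SimulationConfig) -> dict[str, list[str]]:
    """Ground-truth shared / A-only / B-only gene ids and symbols.

    Re-derives the same draws as :func:`generate_disease_associations`, so
    the returned partition is exactly the one planted in the emitted table.
    """
    rng = config.rng("associations")
    universe = gene_universe(config)
    shared, a_only, b_only = _partition_indices(config, rng)
    out = {}
    for name, idx in (("shared", shared), ("A_only", a_only), ("B_only", b_only)):
        out[name] = sorted(universe["gene_id"].to_numpy()[idx])
        out[name + "_symbols"] = sorted(universe["gene_symbol"].to_numpy()[idx])
    return out


# ---------------------------------------------------------------------------
# gene–disease associations
# ---------------------------------------------------------------------------

def _disease_rows(
    rng: np.random.Generator,
    universe: pd.DataFrame,
    gene_idx: np.ndarray,
    disease_label: str,
    n_terms: int,
    extra_term_prob: float = 0.2,
) -> pd.DataFrame:
    n = len(gene_idx)
    if n_terms > n:
        raise ConfigurationError(
            f"{disease_label}: {n_terms} terms but only {n} genes; "
            "every term must be non-empty"
        )
    # primary term per gene; the first n_terms genes pin one gene per term so
    # every term is non-empty, the rest are assigned uniformly
    primary = np.concatenate(
        [np.arange(n_terms), rng.integers(0, n_terms, size=n - n_terms)]
    )
    gene_order = rng.permutation(n)
    terms = np.empty(n, dtype=int)
    terms[gene_order] = primary
    rows = [(gene_idx, terms)]
    # some genes belong to more than one disease term
    extra_mask = rng.random(n) < extra_term_prob
    if extra_mask.any():
        rows.append((gene_idx[extra_mask], rng.integers(0, n_terms, size=extra_mask.sum())))
    gidx = np.concatenate([r[0] for r in rows])
    tidx = np.concatenate([r[1] for r in rows])
    df = pd.DataFrame(
        {
            "gene_id": universe["gene_id"].to_numpy()[gidx],
            "gene_symbol": universe["gene_symbol"].to_numpy()[gidx],
            "term_id": [f"{disease_label}:T{t + 1:02d}" for t in tidx],
            "disease_label": disease_label,
            "source_class": rng.choice(SOURCE_CLASSES, size=len(gidx), p=(0.6, 0.4)),
            "score": rng.uniform(0.0, 1.0, size=len(gidx)).round(6),
        }
    )
    df = df.drop_duplicates(subset=["gene_id", "term_id"])
    return df


def generate_disease_associations(
    config: SimulationConfig,
    disease_A: str = "ParkinsonDisease",
    disease_B: str = "Glioblastoma",
) -> pd.DataFrame:
    """Gene–disease association table for two diseases with a planted overlap.

    The union of genes over each disease's terms has exactly the configured
    size, and the intersection of the two unions has exactly
    ``config.overlap_size`` genes, by construction.
    """
    rng = config.rng("associations")
    universe = gene_universe(config)
    shared, a_only, b_only = _partition_indices(config, rng)
    a_idx = np.concatenate([shared, a_only])
    b_idx = np.concatenate([shared, b_only])
    df_a = _disease_rows(rng, universe, a_idx, disease_A, config.n_terms_A)
    df_b = _disease_rows(rng, universe, b_idx, disease_B, config.n_terms_B)
    df = pd.concat([df_a, df_b], ignore_index=True)
    df = df.sort_values(["disease_label", "term_id", "gene_id"], kind="mergesort")
    logger.info(
        "associations: %d rows, |A|=%d |B|=%d planted overlap=%d",
        len(df), config.disease_A_size, config.disease_B_size, config.overlap_size,
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# miRNA target predictions
# ---------------------------------------------------------------------------

def mirna_ids(config: SimulationConfig) -> list[str]:
    return [f"hsa-miR-sim{i + 1:03d}-5p" for i in range(config.n_mirnas)]


def planted_mirna_ids(config: SimulationConfig) -> list[str]:
    """The miRNAs planted with an elevated shared-target rate."""
    return mirna_ids(config)[: config.n_planted_top]


def generate_target_predictions(
    config: SimulationConfig,
    shared_genes: Sequence[str],
    A_only: Sequence[str],
    B_only: Sequence[str],
) -> pd.DataFrame:
    """Multi-source miRNA→target prediction table.

    Planted-top miRNAs target shared-set genes with
    ``planted_shared_target_prob`` and all other genes with
    ``background_target_prob``; background miRNAs use the background rate
    everywhere.  Each predicted pair is attributed independently to each of
    ``n_sources`` databases with probability ``1 - source_dropout``; a pair
    that would end up sourceless is assigned one source at random so every
    emitted pair appears in at least one source.
    """
    if not len(shared_genes) or not len(A_only) or not len(B_only):
        raise ConfigurationError("all three gene sets must be non-empty")
    rng = config.rng("predictions")
    genes = np.concatenate(
        [np.sort(np.asarray(s, dtype=object)) for s in (shared_genes, A_only, B_only)]
    )
    n_genes = len(genes)
    n_shared = len(shared_genes)
    mirnas = mirna_ids(config)

    probs = np.full((config.n_mirnas, n_genes), config.background_target_prob)
    probs[: config.n_planted_top, :n_shared] = config.planted_shared_target_prob
    pair_mask = rng.random((config.n_mirnas, n_genes)) < probs
    mi, gi = np.nonzero(pair_mask)
    n_pairs = len(mi)
    if n_pairs == 0:
        raise ConfigurationError("no miRNA-target pairs sampled; raise the probabilities")

    src_mask = rng.random((n_pairs, config.n_sources)) < (1.0 - config.source_dropout)
    orphan = ~src_mask.any(axis=1)
    if orphan.any():
        forced = rng.integers(0, config.n_sources, size=int(orphan.sum()))
        src_mask[np.nonzero(orphan)[0], forced] = True
    pi, si = np.nonzero(src_mask)

    df = pd.DataFrame(
        {
            "mirna_id": np.asarray(mirnas, dtype=object)[mi[pi]],
            "gene_symbol": genes[gi[pi]],
            "source_db": [f"sourceDB{s + 1:02d}" for s in si],
            "score": rng.uniform(0.0, 1.0, size=len(pi)).round(6),
        }
    )
    df = df.sort_values(["mirna_id", "gene_symbol", "source_db"], kind="mergesort")
    logger.info(
        "predictions: %d pairs, %d rows over %d sources",
        n_pairs, len(df), config.n_sources,
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT gene-set library
# ---------------------------------------------------------------------------

def generate_gmt_library(
    config: SimulationConfig,
    planted_gene_pool: Sequence[str],
    universe: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """GMT-style library with planted enriched terms.

    Planted terms draw at least ``planted_pool_fraction`` of their members
    from ``planted_gene_pool``; background terms draw uniformly from the
    universe.
    """
    pool = sorted(set(planted_gene_pool))
    if not pool:
        raise ConfigurationError("planted gene pool is empty")
    if universe is None:
        universe = gene_universe(config)["gene_symbol"].tolist()
    universe = np.asarray(sorted(set(universe)), dtype=object)
    rng = config.rng("gmt")
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ConfigurationError("term size range exceeds the gene universe")
    library: dict[str, list[str]] = {}
    for i in range(config.planted_enriched_terms):
        size = int(rng.integers(lo, hi + 1))
        n_pool = min(math.ceil(config.planted_pool_fraction * size), len(pool))
        members = list(rng.choice(np.asarray(pool, dtype=object), size=n_pool, replace=False))
        rest = universe[~np.isin(universe, members)]
        n_bg = min(size - n_pool, len(rest))
        if n_bg > 0:
            members += list(rng.choice(rest, size=n_bg, replace=False))
        library[f"PLANTED_TERM_{i + 1:02d}"] = sorted(members)
    for i in range(config.n_library_terms - config.planted_enriched_terms):
        size = int(rng.integers(lo, hi + 1))
        library[f"TERM_{i + 1:03d}"] = sorted(
            rng.choice(universe, size=size, replace=False)
        )
    return library


def write_gmt(library: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, f"{term} (synthetic)"] + list(genes))
        for term, genes in library.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    library: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {line[:60]!r}")
        library[parts[0]] = [g for g in parts[2:] if g]
    return library


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def _flatten_nodes(node_groups) -> list[str]:
    if isinstance(node_groups, Mapping):
        seq: list[str] = []
        for group in node_groups.values():
            seq.extend(group)
    else:
        seq = list(node_groups)
    seen: dict[str, None] = {}
    for n in seq:
        seen.setdefault(n)
    return list(seen)


def generate_interactome(
    config: SimulationConfig,
    node_groups: Mapping[str, Sequence[str]] | Sequence[str],
) -> pd.DataFrame:
    """Scored undirected edge list with planted hubs.

    Preferential-attachment mode grows the graph from a complete core of the
    first ``n_planted_hubs`` nodes; every subsequent node links once to a
    uniformly chosen planted hub and ``pa_edges_per_node - 1`` times
    preferentially by degree, so the planted hubs receive the highest
    expected degree by construction.  Configuration mode realizes the
    prescribed degree sequence exactly (Havel–Hakimi construction followed
    by degree-preserving double edge swaps).
    """
    import networkx as nx

    nodes = _flatten_nodes(node_groups)
    if len(nodes) < max(2, config.n_planted_hubs):
        raise ConfigurationError(
            f"need at least max(2, n_planted_hubs) nodes, got {len(nodes)}"
        )
    rng = config.rng("interactome")

    if config.network_model == "preferential_attachment":
        hubs = list(range(config.n_planted_hubs))
        graph = nx.complete_graph(hubs)
        repeated: list[int] = [h for e in graph.edges for h in e] or hubs[:]
        m = config.pa_edges_per_node
        for v in range(config.n_planted_hubs, len(nodes)):
            targets = {int(rng.choice(hubs))}
            existing = list(graph.nodes)
            while len(targets) < min(m, len(existing)):
                targets.add(int(repeated[rng.integers(0, len(repeated))]))
            for t in targets:
                graph.add_edge(v, t)
                repeated.extend([v, t])
    elif config.network_model == "configuration":
        if config.degree_sequence is None:
            raise ConfigurationError("configuration model requires degree_sequence")
        seq = list(config.degree_sequence)
        if len(seq) != len(nodes):
            raise ConfigurationError(
                f"degree sequence length {len(seq)} != node count {len(nodes)}"
            )
        graph = nx.havel_hakimi_graph(seq)
        if graph.number_of_edges() >= 2:
            nx.double_edge_swap(
                graph,
                nswap=2 * graph.number_of_edges(),
                max_tries=200 * graph.number_of_edges(),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(config.network_model)

    name = dict(enumerate(nodes))
    records = []
    for u, v in graph.edges:
        a, b = sorted((name[u], name[v]))
        records.append((a, b))
    df = pd.DataFrame(sorted(set(records)), columns=["geneA", "geneB"])
    df["confidence"] = rng.uniform(0.0, 1.0, size=len(df)).round(6)
    logger.info("interactome: %d nodes, %d edges (%s)", len(nodes), len(df), config.network_model)
    return df


def planted_hub_ids(
    config: SimulationConfig,
    node_groups: Mapping[str, Sequence[str]] | Sequence[str],
) -> list[str]:
    return _flatten_nodes(node_groups)[: config.n_planted_hubs]


# ---------------------------------------------------------------------------
# qPCR Ct data
# ---------------------------------------------------------------------------

def generate_qpcr_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Three-group plasma and two-compartment tissue Ct table.

    The target Ct is ``baseline - effect / log2(E) + noise`` so the planted
    log2 fold-change is recoverable through efficiency-adjusted relative
    quantification.  Reference-gene (U6) and spike-in (cel-miR-39-3p) rows
    are drawn with their own small SDs; analytes listed as undetectable in
    plasma are emitted with Ct > 40.
    """
    q = config.qpcr
    q.validate()
    rng = config.rng("qpcr")
    rows: list[tuple] = []

    def ct_for(analyte: str, effect: float) -> float:
        e = q.efficiency(analyte)
        return q.baseline_ct - effect / math.log2(e) + rng.normal(0.0, q.within_sd)

    plasma_groups = [("control", q.n_control), ("PD", q.n_pd), ("glioma", q.n_glioma)]
    plasma_analytes = sorted(set(q.plasma_effects) | set(q.undetectable_plasma))
    for group, n in plasma_groups:
        for i in range(n):
            sample = f"PL-{group}-{i + 1:02d}"
            for analyte in plasma_analytes:
                if analyte in q.undetectable_plasma:
                    ct = CT_UNDETECTABLE + 0.5 + rng.exponential(1.0)
                else:
                    effect = q.plasma_effects[analyte].get(group, 0.0)
                    ct = ct_for(analyte, effect)
                rows.append((sample, group, "plasma", analyte, ct, q.efficiency(analyte)))
            rows.append(
                (sample, group, "plasma", q.reference_analyte,
                 q.reference_ct + rng.normal(0.0, q.reference_sd),
                 q.efficiency(q.reference_analyte))
            )
            rows.append(
                (sample, group, "plasma", q.spike_analyte,
                 q.spike_ct + rng.normal(0.0, q.spike_sd),
                 q.efficiency(q.spike_analyte))
            )

    for compartment in ("tumor", "peritumoral"):
        for i in range(q.n_tissue):
            sample = f"TS-{compartment}-{i + 1:02d}"
            for analyte, effect in sorted(q.tissue_effects.items()):
                eff = effect if compartment == "tumor" else 0.0
                rows.append(
                    (sample, "glioma", compartment, analyte,
                     ct_for(analyte, eff), q.efficiency(analyte))
                )
            rows.append(
                (sample, "glioma", compartment, q.reference_analyte,
                 q.reference_ct + rng.normal(0.0, q.reference_sd),
                 q.efficiency(q.reference_analyte))
            )

    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "compartment", "analyte", "ct", "efficiency"],
    )
    df["ct"] = df["ct"].round(4)
    return df


def generate_elisa_dataset(
    config: SimulationConfig,
    tumor_mean_pg_per_ng: float = 0.08,
    peritumoral_mean_pg_per_ng: float = 0.036,
    log_sd: float = 0.3,
    assay_volume_ml: float = 0.1,
) -> pd.DataFrame:
    """Tumor/peritumoral p53-style ELISA table with planted pg/ng means.

    Concentrations are back-computed from a log-normal pg/ng level and a
    per-sample total-protein amount so that normalization recovers the
    planted compartment means in expectation of the log scale.
    """
    rng = config.rng("elisa")
    rows = []
    for compartment, mean in (
        ("tumor", tumor_mean_pg_per_ng),
        ("peritumoral", peritumoral_mean_pg_per_ng),
    ):
        for i in range(config.qpcr.n_tissue):
            protein_ng = rng.uniform(300.0, 600.0)
            normalized = mean * math.exp(rng.normal(0.0, log_sd))
            conc = normalized * protein_ng / assay_volume_ml
            rows.append(
                (f"TS-{compartment}-{i + 1:02d}", compartment,
                 round(conc, 4), assay_volume_ml, round(protein_ng, 2))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "compartment", "concentration_pg_per_ml",
            "assay_volume_ml", "total_protein_ng",
        ],
    )


# ---------------------------------------------------------------------------
# emit everything to disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write every synthetic input under ``outdir`` and return a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assoc = generate_disease_associations(config)
    partition = planted_partition(config)
    preds = generate_target_predictions(
        config,
        partition["shared_symbols"],
        partition["A_only_symbols"],
        partition["B_only_symbols"],
    )
    # the planted enrichment pool is the shared-gene symbol set
    library = generate_gmt_library(config, partition["shared_symbols"])
    # interactome over the shared genes, planted hubs first
    interactome = generate_interactome(config, partition["shared_symbols"][: config.n_network_nodes])
    qpcr = generate_qpcr_dataset(config)
    elisa = generate_elisa_dataset(config)

    files = {
        "associations.tsv": lambda p: assoc.to_csv(p, sep="\t", index=False),
        "predictions.tsv": lambda p: preds.to_csv(p, sep="\t", index=False),
        "library.gmt": lambda p: write_gmt(library, p),
        "interactome.tsv": lambda p: interactome.to_csv(p, sep="\t", index=False),
        "qpcr_ct.csv": lambda p: qpcr.to_csv(p, index=False),
        "elisa.csv": lambda p: elisa.to_csv(p, index=False),
        "planted_truth.json": lambda p: Path(p).write_text(
            json.dumps(
                {
                    "partition_sizes": {
                        "shared": len(partition["shared"]),
                        "A_only": len(partition["A_only"]),
                        "B_only": len(partition["B_only"]),
                    },
                    "planted_mirnas": planted_mirna_ids(config),
                    "planted_terms": [t for t in library if t.startswith("PLANTED")],
                    "planted_hubs": planted_hub_ids(
                        config, partition["shared_symbols"][: config.n_network_nodes]
                    ),
                },
                indent=2,
                sort_keys=True,
            )
        ),
        "simulation_config.json": lambda p: Path(p).write_text(
            json.dumps(config_to_dict(config), indent=2, sort_keys=True)
        ),
    }
    manifest = {"stage": "simulate", "outputs": {}}
    for name, writer in files.items():
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
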