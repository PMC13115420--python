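"""End-to-end orchestration: simulate → genesets → rank → enrich → network →
expression, with structured logging and a deterministic run manifest.

Stages communicate only through declared files under the run's output
directory, so each stage can also be run in isolation against a directory
produced by an earlier invocation.  The manifest records every output file
with its sha256 checksum; identical config+seed yields byte-identical
manifests.  Per-stage wall time is logged, not written to the manifest,
precisely so the manifest stays reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import expression as expr
from . import gene_sets as gs
from . import network as net
from . import ranking as rk
from . import synthetic as syn
from .config import RunConfig

logger = logging.getLogger("mirshare.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _inputs_dir(config: RunConfig) -> Path:
    return Path(config.input_paths.get("inputs", config.outdir / "inputs"))


def _read_lines(path: Path) -> list[str]:
    return [line for line in path.read_text().splitlines() if line]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    indir = outdir / "inputs"
    syn.generate_all(config.simulate, indir)
    return sorted(p for p in indir.iterdir() if p.is_file())


def stage_genesets(config: RunConfig, outdir: Path) -> list[Path]:
    indir = _inputs_dir(config)
    assocs = gs.read_associations(indir / "associations.tsv")
    labels = sorted({a.disease_label for a in assocs})
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 diseases, found {labels}")
    label_a, label_b = labels[-1], labels[0]  # ParkinsonDisease, Glioblastoma
    if "Parkinson" not in label_a and "Parkinson" in label_b:
        label_a, label_b = label_b, label_a
    set_a = gs.build_disease_set(assocs, gs.terms_for_disease(assocs, label_a), label_a)
    set_b = gs.build_disease_set(assocs, gs.terms_for_disease(assocs, label_b), label_b)
    shared = gs.intersect(set_a, set_b)

    gdir = outdir / "genesets"
    gdir.mkdir(parents=True, exist_ok=True)
    gs.write_gene_set(set_a, gdir / "disease_A.txt")
    gs.write_gene_set(set_b, gdir / "disease_B.txt")
    symbol_of = {a.gene_id: a.gene_symbol for a in assocs}
    for name, ids in (
        ("shared", shared.shared),
        ("A_only", shared.A_only),
        ("B_only", shared.B_only),
    ):
        (gdir / f"{name}.txt").write_text("\n".join(sorted(ids)) + "\n")
        (gdir / f"{name}_symbols.txt").write_text(
            "\n".join(sorted(symbol_of[g] for g in ids)) + "\n"
        )
    summary = {
        "disease_A": {"label": label_a, "n_terms": len(set_a.term_ids), "n_genes": len(set_a)},
        "disease_B": {"label": label_b, "n_terms": len(set_b.term_ids), "n_genes": len(set_b)},
        "n_shared": len(shared.shared),
        "n_A_only": len(shared.A_only),
        "n_B_only": len(shared.B_only),
    }
    (gdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("genesets: %s", summary)
    return sorted(p for p in gdir.iterdir() if p.is_file())


def _load_symbol_sets(config: RunConfig, outdir: Path):
    gdir = outdir / "genesets"
    shared = _read_lines(gdir / "shared_symbols.txt")
    a_only = _read_lines(gdir / "A_only_symbols.txt")
    b_only = _read_lines(gdir / "B_only_symbols.txt")
    return shared, a_only, b_only


def stage_rank(config: RunConfig, outdir: Path) -> list[Path]:
    indir = _inputs_dir(config)
    preds = pd.read_csv(indir / "predictions.tsv", sep="\t")
    shared, a_only, b_only = _load_symbol_sets(config, outdir)
    pairs = rk.aggregate_predictions(preds, min_sources=config.min_sources)
    table = rk.build_rank_table(
        pairs,
        shared_genes=shared,
        universe_B=set(shared) | set(b_only),
        universe_A=set(shared) | set(a_only),
    )
    ranked = rk.rank_mirnas(table)
    ranked = rk.oner_cluster(ranked)
    top = rk.select_top_decile(ranked, config.decile_fraction)

    # pathway-style annotation against the planted library terms
    library = syn.read_gmt(indir / "library.gmt")
    pathway_lists = {t: g for t, g in library.items() if t.startswith("PLANTED")}
    hits = {}
    if pathway_lists:
        by_mirna = rk.targets_by_mirna(pairs)
        hits = {
            m: rk.annotate_pathways(by_mirna.get(m, set()), pathway_lists)
            for m in ranked["mirna_id"]
        }
    rdir = outdir / "ranking"
    rdir.mkdir(parents=True, exist_ok=True)
    rk.write_ranking(ranked, rdir / "ranking.tsv", hits)
    rk.write_ranking(top, rdir / "top_decile.tsv")
    logger.info("rank: %d miRNAs ranked, top decile = %d", len(ranked), len(top))
    return sorted(p for p in rdir.iterdir() if p.is_file())


def _top_two_targets(config: RunConfig, outdir: Path):
    indir = _inputs_dir(config)
    preds = pd.read_csv(indir / "predictions.tsv", sep="\t")
    pairs = rk.aggregate_predictions(preds, min_sources=config.min_sources)
    top = pd.read_csv(outdir / "ranking" / "top_decile.tsv", sep="\t")
    mir_a, mir_b = top["mirna_id"].iloc[0], top["mirna_id"].iloc[1 if len(top) > 1 else 0]
    by_mirna = rk.targets_by_mirna(pairs)
    return mir_a, mir_b, by_mirna.get(mir_a, set()), by_mirna.get(mir_b, set())


def stage_enrich(config: RunConfig, outdir: Path) -> list[Path]:
    indir = _inputs_dir(config)
    library = syn.read_gmt(indir / "library.gmt")
    mir_a, mir_b, targets_a, targets_b = _top_two_targets(config, outdir)
    frame = enr.shared_target_enrichment(
        targets_a,
        targets_b,
        libraries={"synthetic_library": library},
        background_size=config.background_size,
        top_k=config.top_k,
        alpha=config.alpha,
    )
    edir = outdir / "enrichment"
    edir.mkdir(parents=True, exist_ok=True)
    enr.write_results(frame, edir / "enrichment.tsv")
    enr.write_results(enr.dotplot_summary(frame), edir / "dotplot_summary.tsv")
    logger.info("enrich: %s vs %s, %d significant terms", mir_a, mir_b, len(frame))
    return sorted(p for p in edir.iterdir() if p.is_file())


def stage_network(config: RunConfig, outdir: Path) -> list[Path]:
    indir = _inputs_dir(config)
    edges = pd.read_csv(indir / "interactome.tsv", sep="\t")
    shared, _, _ = _load_symbol_sets(config, outdir)
    _, _, targets_a, targets_b = _top_two_targets(config, outdir)
    network = net.build_network(
        edges, targets_a, targets_b, shared, min_confidence=config.min_confidence
    )
    selections = net.select_hubs(
        network, n_shared=config.n_hub_shared, n_each=config.n_hub_each
    )
    ndir = outdir / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    net.write_network(selections, network, ndir / "nodes.tsv", ndir / "edges_within.tsv")
    return sorted(p for p in ndir.iterdir() if p.is_file())


def stage_expression(config: RunConfig, outdir: Path) -> list[Path]:
    indir = _inputs_dir(config)
    ct = pd.read_csv(indir / "qpcr_ct.csv")
    xdir = outdir / "expression"
    xdir.mkdir(parents=True, exist_ok=True)

    spike = ct[(ct["analyte"] == "cel-miR-39-3p") & (ct["compartment"] == "plasma")]
    qc = expr.spike_in_qc(dict(zip(spike["sample_id"], spike["ct"])))
    qc.to_csv(xdir / "spike_qc.csv", index=False)

    ratios = expr.quantify_dataset(ct, ct_cutoff=config.ct_cutoff)
    ratios.to_csv(xdir / "relative_expression.csv", index=False)

    stat_rows = []
    box = {}
    plasma = ratios[ratios["compartment"] == "plasma"]
    for analyte, sub in plasma.groupby("analyte"):
        groups = {g: v["ratio"].tolist() for g, v in sub.groupby("group")}
        finite = {g: [x for x in v if np.isfinite(x)] for g, v in groups.items()}
        if any(len(v) < 2 for v in finite.values()):
            stat_rows.append({"analyte": analyte, "scope": "plasma", "note": "insufficient detectable data"})
            continue
        comp = expr.anova_lsd(groups, analyte=analyte)
        row = {
            "analyte": analyte, "scope": "plasma",
            "F": round(comp.F, 6), "p_overall": round(comp.p_overall, 8),
        }
        for g, m in sorted(comp.group_means.items()):
            row[f"mean_{g}"] = round(m, 6)
        for (g1, g2), p in sorted(comp.pairwise_p.items()):
            row[f"lsd_p_{g1}_vs_{g2}"] = round(p, 8)
        for (g1, g2), f in sorted(comp.fold_changes.items()):
            row[f"fold_{g1}_vs_{g2}"] = expr.round_half_up(f, 2)
        stat_rows.append(row)
        box[analyte] = {
            g: expr.boxplot_summary(v) for g, v in finite.items() if v
        }
    tissue = ratios[ratios["compartment"].isin(["tumor", "peritumoral"])]
    for analyte, sub in tissue.groupby("analyte"):
        arms = {c: v["ratio"].tolist() for c, v in sub.groupby("compartment")}
        try:
            t, p = expr.two_sample_t(arms.get("tumor", []), arms.get("peritumoral", []))
        except ValueError:
            stat_rows.append({"analyte": analyte, "scope": "tissue", "note": "insufficient detectable data"})
            continue
        means = {c: float(np.nanmean(v)) for c, v in arms.items()}
        fold = expr.group_fold_change(means, "tumor", "peritumoral")
        stat_rows.append(
            {
                "analyte": analyte, "scope": "tissue",
                "t": round(t, 6), "p_overall": round(p, 8),
                "mean_tumor": round(means["tumor"], 6),
                "mean_peritumoral": round(means["peritumoral"], 6),
                "fold_tumor_vs_peritumoral": fold.reported,
            }
        )
    elisa_path = indir / "elisa.csv"
    if elisa_path.exists():
        elisa = pd.read_csv(elisa_path)
        measurements = [
            expr.elisa_normalize(
                row.concentration_pg_per_ml, row.assay_volume_ml, row.total_protein_ng,
                sample_id=row.sample_id, compartment=row.compartment,
            )
            for row in elisa.itertuples(index=False)
        ]
        edf = pd.DataFrame([m.__dict__ for m in measurements])
        edf.to_csv(xdir / "elisa_normalized.csv", index=False)
        arms = {
            c: v["normalized_pg_per_ng"].tolist()
            for c, v in edf.groupby("compartment")
        }
        t, p = expr.two_sample_t(arms["tumor"], arms["peritumoral"])
        means = {c: float(np.mean(v)) for c, v in arms.items()}
        fold = expr.group_fold_change(means, "tumor", "peritumoral", round_to=1)
        stat_rows.append(
            {
                "analyte": "p53", "scope": "elisa",
                "t": round(t, 6), "p_overall": round(p, 8),
                "mean_tumor": round(means["tumor"], 6),
                "mean_peritumoral": round(means["peritumoral"], 6),
                "fold_tumor_vs_peritumoral": fold.reported,
            }
        )
    pd.DataFrame(stat_rows).to_csv(xdir / "group_stats.tsv", sep="\t", index=False)
    (xdir / "boxplot_summary.json").write_text(json.dumps(box, indent=2, sort_keys=True))
    return sorted(p for p in xdir.iterdir() if p.is_file())


STAGES: dict[str, Callable[[RunConfig, Path], list[Path]]] = {
    "simulate": stage_simulate,
    "genesets": stage_genesets,
    "rank": stage_rank,
    "enrich": stage_enrich,
    "network": stage_network,
    "expression": stage_expression,
}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    On stage failure the partial outputs are retained under a
    ``FAILED_<stage>`` marker file and a :class:`StageError` is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    to_run = [s for s in (stages or config.stages) if s in STAGES]
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    for stage in to_run:
        start = time.perf_counter()
        try:
            outputs = STAGES[stage](config, outdir)
        except Exception as exc:
            (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
            raise StageError(stage, exc) from exc
        elapsed = time.perf_counter() - start
        logger.info("stage %s finished in %.2fs (%d files)", stage, elapsed, len(outputs))
        rel = {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
        manifest["stages"].append({"stage": stage, "outputs": sorted(rel)})
        manifest["files"].update(rel)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
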