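"""Configuration objects and validation for the simulation and the pipeline.

Two layers of configuration exist:

* :class:`SimulationConfig` — parameters of the synthetic-data generators
  (disease set sizes, planted miRNA signal, source databases, interactome
  model, qPCR effect sizes).  Defaults reproduce the scale of the reference
  study: 2177 Parkinson's-disease genes over 28 terms, 3377 glioblastoma
  genes over 14 terms, 953 shared genes, 14 prediction source databases.
* :class:`RunConfig` — pipeline-level thresholds (minimum source count,
  enrichment alpha, top-k, decile fraction, interaction confidence cutoff,
  hub list sizes, Ct detectability cutoff), stage toggles, paths and seed.

Both can be loaded from YAML or JSON files with :func:`load_run_config`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

logger = logging.getLogger("mirshare")

#: Ct value above which an analyte is considered undetectable (cycles).
CT_UNDETECTABLE = 40.0

#: Default background ("human genome") size for enrichment tests.
DEFAULT_GENOME_SIZE = 20_000

#: ELISA kit detection range, pg/mL.
ELISA_RANGE_PG_PER_ML = (9.38, 600.0)

# Stable RNG stream offsets, one per generator, so adding a generator never
# perturbs another generator's output for the same seed.
RNG_OFFSETS = {
    "associations": 11,
    "predictions": 23,
    "gmt": 37,
    "interactome": 47,
    "qpcr": 59,
    "elisa": 71,
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates a documented invariant."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class QpcrConfig:
    """Planted qPCR study design.

    Effects are log2 fold-changes of the target analyte relative to the
    calibrator group (plasma: control/discopathy; tissue: peritumoral).
    Noise is Gaussian on the Ct scale, which is multiplicative on the
    expression scale — the conventional qPCR error model.  Default effect
    sizes are the group-mean ratios reported for the study cohort
    (plasma miR-16-5p 1.76/2.0/5.7, miR-32-5p 1.1/1.4/3.6; tissue
    miR-16-5p 1.1/1.6), so the planted truth matches the published
    fold-changes (3.24, 2.85, 1.45 ...).
    """

    n_control: int = 10
    n_pd: int = 12
    n_glioma: int = 13
    n_tissue: int = 13
    #: analyte -> {group: log2 fold-change vs control} for plasma
    plasma_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "hsa-miR-16-5p": {"PD": math.log2(2.0 / 1.76), "glioma": math.log2(5.7 / 1.76)},
            "hsa-miR-32-5p": {"PD": math.log2(1.4 / 1.1), "glioma": math.log2(3.6 / 1.1)},
            "hsa-miR-29a-3p": {"PD": 0.0, "glioma": 0.0},
            "hsa-miR-34a-5p": {"PD": 0.0, "glioma": 0.0},
        }
    )
    #: analyte -> log2 fold-change tumor vs peritumoral for tissue
    tissue_effects: dict[str, float] = field(
        default_factory=lambda: {
            "hsa-miR-16-5p": math.log2(1.6 / 1.1),
            "hsa-miR-32-5p": 0.0,
            "hsa-miR-29a-3p": 0.0,
            "hsa-miR-34a-5p": 0.0,
            "hsa-miR-124-3p": 0.0,
            "hsa-miR-548c-3p": 0.0,
        }
    )
    #: analytes planted as undetectable (Ct > 40) in plasma
    undetectable_plasma: tuple[str, ...] = ("hsa-miR-124-3p", "hsa-miR-548c-3p")
    within_sd: float = 0.3  # Ct units
    reference_sd: float = 0.1
    spike_sd: float = 0.15
    #: per-analyte amplification efficiency; analytes not listed default to 2.0
    efficiencies: dict[str, float] = field(default_factory=dict)
    default_efficiency: float = 2.0
    baseline_ct: float = 28.0
    reference_ct: float = 20.0
    spike_ct: float = 22.0
    reference_analyte: str = "U6"
    spike_analyte: str = "cel-miR-39-3p"

    def efficiency(self, analyte: str) -> float:
        return self.efficiencies.get(analyte, self.default_efficiency)

    def validate(self) -> None:
        for n in (self.n_control, self.n_pd, self.n_glioma, self.n_tissue):
            if n < 2:
                raise ConfigurationError("each qPCR group needs at least 2 samples")
        for analyte in list(self.efficiencies) + [None]:
            e = self.efficiency(analyte) if analyte else self.default_efficiency
            if not (1.0 < e <= 2.2):
                raise ConfigurationError(
                    f"amplification efficiency {e} outside (1, 2.2] for {analyte!r}"
                )
        for sd in (self.within_sd, self.reference_sd, self.spike_sd):
            if sd < 0:
                raise ConfigurationError("Ct standard deviations must be >= 0")


@dataclass
class SimulationConfig:
    """Parameters of every synthetic-data generator.

    Disease A is the Parkinson's-disease-like set, disease B the
    glioblastoma-like set.  The overlap is planted exactly, not sampled,
    so the configured set sizes are reproduced by construction.
    """

    seed: int = 0
    n_genes_universe: int = 10_000
    disease_A_size: int = 2177
    disease_B_size: int = 3377
    overlap_size: int = 953
    n_terms_A: int = 28
    n_terms_B: int = 14
    # miRNA target predictions
    n_mirnas: int = 140
    n_planted_top: int = 14
    planted_shared_target_prob: float = 0.5
    background_target_prob: float = 0.05
    n_sources: int = 14
    source_dropout: float = 0.3
    # GMT library
    n_library_terms: int = 50
    planted_enriched_terms: int = 1
    term_size_range: tuple[int, int] = (20, 120)
    planted_pool_fraction: float = 0.6
    # interactome
    network_model: str = "preferential_attachment"
    n_network_nodes: int = 100
    n_planted_hubs: int = 3
    pa_edges_per_node: int = 3
    degree_sequence: tuple[int, ...] | None = None
    # qPCR
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.overlap_size > min(self.disease_A_size, self.disease_B_size):
            raise ConfigurationError(
                "overlap_size must not exceed either disease set size "
                f"({self.overlap_size} > min({self.disease_A_size}, {self.disease_B_size}))"
            )
        union = self.disease_A_size + self.disease_B_size - self.overlap_size
        if union > self.n_genes_universe:
            raise ConfigurationError(
                f"gene universe ({self.n_genes_universe}) smaller than the "
                f"disease union ({union})"
            )
        for name in ("planted_shared_target_prob", "background_target_prob"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {p}")
        if not (0.0 <= self.source_dropout < 1.0):
            raise ConfigurationError("source_dropout must lie in [0, 1)")
        for name in ("n_terms_A", "n_terms_B", "n_sources"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_planted_top > self.n_mirnas:
            raise ConfigurationError("n_planted_top cannot exceed n_mirnas")
        if self.network_model not in ("preferential_attachment", "configuration"):
            raise ConfigurationError(
                f"unknown network_model {self.network_model!r}"
            )
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("term_size_range must satisfy 0 < lo <= hi")
        self.qpcr.validate()

    def rng(self, generator: str):
        """Per-generator RNG stream: `seed` plus a stable generator offset."""
        import numpy as np

        return np.random.default_rng([int(self.seed), RNG_OFFSETS[generator]])


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (thresholds default to the values
    used in the reference analysis where one is stated: top 10% of miRNAs,
    top 5 terms per library, adjusted p < 0.05, top 20/15 hub genes, Ct 40)."""

    outdir: Path = Path("mirshare_run")
    seed: int = 0
    simulate: SimulationConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)
    stages: tuple[str, ...] = (
        "simulate",
        "genesets",
        "rank",
        "enrich",
        "network",
        "expression",
    )
    min_sources: int = 1
    alpha: float = 0.05
    top_k: int = 5
    decile_fraction: float = 0.10
    min_confidence: float = 0.4
    n_hub_shared: int = 20
    n_hub_each: int = 15
    ct_cutoff: float = CT_UNDETECTABLE
    background_size: int = DEFAULT_GENOME_SIZE

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None and "simulate" in self.stages:
            self.simulate = SimulationConfig(seed=self.seed)
        self.validate()

    def validate(self) -> None:
        if self.min_sources < 1:
            raise ConfigurationError("min_sources must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if not (0.0 < self.decile_fraction <= 1.0):
            raise ConfigurationError("decile_fraction must lie in (0, 1]")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ConfigurationError("min_confidence must lie in [0, 1]")
        known = set(RunConfig.__dataclass_fields__["stages"].default)
        unknown = [s for s in self.stages if s not in known]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        if "simulate" not in self.stages:
            for key, path in self.input_paths.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"input path for {key!r} missing: {path}")


def _as_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(config: Any) -> dict:
    """Serialize a config dataclass to plain JSON/YAML-compatible types."""
    return _as_plain(config)


def simulation_config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    data = dict(data)
    qpcr = data.pop("qpcr", None)
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(SimulationConfig):
        if f.name in data:
            value = data.pop(f.name)
            if f.name in ("term_size_range", "degree_sequence") and value is not None:
                value = tuple(value)
            kwargs[f.name] = value
    if data:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(data)}")
    if qpcr is not None:
        qk = {f.name: qpcr[f.name] for f in dataclasses.fields(QpcrConfig) if f.name in qpcr}
        if "undetectable_plasma" in qk:
            qk["undetectable_plasma"] = tuple(qk["undetectable_plasma"])
        kwargs["qpcr"] = QpcrConfig(**qk)
    return SimulationConfig(**kwargs)


def run_config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data)
    sim = data.pop("simulate", None)
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in data:
            value = data.pop(f.name)
            if f.name == "stages":
                value = tuple(value)
            kwargs[f.name] = value
    if data:
        raise ConfigurationError(f"unknown run config keys: {sorted(data)}")
    if sim is not None:
        if "seed" not in sim and "seed" in kwargs:
            sim = {**sim, "seed": kwargs["seed"]}
        kwargs["simulate"] = simulation_config_from_dict(sim)
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, Mapping):
        raise FormatError(f"config file {path} does not contain a mapping")
    return run_config_from_dict(data)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
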