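"""Generator-level checks: planted structure is present, exact where the
construction is exact, and byte-identical under a fixed seed."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirshare.config import ConfigurationError, QpcrConfig, SimulationConfig
from mirshare.expression import quantify_dataset
from mirshare.synthetic import (
    generate_disease_associations,
    generate_gmt_library,
    generate_interactome,
    generate_qpcr_dataset,
    generate_target_predictions,
    planted_mirna_ids,
    planted_partition,
    write_gmt,
)


def _recount_sets(assoc: pd.DataFrame):
    by_disease = {
        label: set(sub["gene_id"]) for label, sub in assoc.groupby("disease_label")
    }
    (a, b) = sorted(by_disease.values(), key=len)
    return a, b


class TestDiseaseAssociations:
    @pytest.mark.parametrize(
        "sizes, seed",
        [((10, 12, 4), 7), ((25, 40, 10), 3), ((8, 8, 8), 11)],
    )
    def test_recounted_sizes_match_configuration(self, sizes, seed):
        a_size, b_size, overlap = sizes
        config = SimulationConfig(
            seed=seed, n_genes_universe=200,
            disease_A_size=a_size, disease_B_size=b_size, overlap_size=overlap,
            n_terms_A=3, n_terms_B=2,
        )
        assoc = generate_disease_associations(config)
        small, large = _recount_sets(assoc)
        assert (len(small), len(large)) == (min(a_size, b_size), max(a_size, b_size))
        assert len(small & large) == overlap

    def test_zero_overlap_gives_disjoint_unions(self):
        config = SimulationConfig(
            seed=2, n_genes_universe=100, disease_A_size=20, disease_B_size=30,
            overlap_size=0, n_terms_A=2, n_terms_B=2,
        )
        a, b = _recount_sets(generate_disease_associations(config))
        assert not a & b

    def test_every_term_nonempty_and_rows_well_formed(self, small_config):
        assoc = generate_disease_associations(small_config)
        for label, n_terms in (("ParkinsonDisease", 4), ("Glioblastoma", 3)):
            terms = set(assoc.loc[assoc.disease_label == label, "term_id"])
            assert len(terms) == n_terms
        assert set(assoc["source_class"]) <= {"curated", "literature"}
        assert assoc["score"].between(0, 1).all()
        assert not assoc.duplicated(["gene_id", "term_id"]).any()

    def test_overlap_larger_than_either_set_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(disease_A_size=10, disease_B_size=20, overlap_size=11,
                             n_genes_universe=100)

    def test_partition_matches_emitted_table(self, small_config):
        part = planted_partition(small_config)
        a, b = _recount_sets(generate_disease_associations(small_config))
        # a is the smaller (disease A) set here
        assert a & b == set(part["shared"])
        assert a - b == set(part["A_only"])
        assert b - a == set(part["B_only"])


class TestTargetPredictions:
    def test_planted_shared_count_near_binomial_mean(self):
        shared = [f"S{i}" for i in range(100)]
        counts = []
        for seed in range(10):
            config = SimulationConfig(
                seed=seed, n_mirnas=5, n_planted_top=1,
                planted_shared_target_prob=0.5, background_target_prob=0.05,
            )
            preds = generate_target_predictions(config, shared, ["a1", "a2"], ["b1", "b2"])
            planted = planted_mirna_ids(config)[0]
            sub = preds[(preds.mirna_id == planted) & preds.gene_symbol.isin(shared)]
            counts.append(sub["gene_symbol"].nunique())
        # Binomial(100, 0.5): mean of 10 seeds within 3 SE of 50
        assert abs(np.mean(counts) - 50) < 3 * 5 / math.sqrt(10)

    def test_zero_dropout_lists_every_pair_in_all_sources(self, small_config):
        config = SimulationConfig(
            seed=1, n_mirnas=4, n_planted_top=1, n_sources=5, source_dropout=0.0
        )
        preds = generate_target_predictions(config, ["s1", "s2", "s3"], ["a1"], ["b1"])
        per_pair = preds.groupby(["mirna_id", "gene_symbol"])["source_db"].nunique()
        assert (per_pair == 5).all()

    def test_every_pair_has_at_least_one_source(self, small_config):
        config = SimulationConfig(seed=3, n_mirnas=10, n_planted_top=2,
                                  source_dropout=0.95, n_sources=3)
        preds = generate_target_predictions(
            config, [f"s{i}" for i in range(30)], ["a1", "a2"], ["b1", "b2"]
        )
        assert (preds.groupby(["mirna_id", "gene_symbol"])["source_db"].nunique() >= 1).all()

    def test_no_planted_top_stays_below_binomial_bound(self):
        """Without planted miRNAs no shared count exceeds the binomial
        upper 99.9% bound across 20 seeds."""
        shared = [f"S{i}" for i in range(200)]
        bound = stats.binom.ppf(0.999, len(shared), 0.05)
        worst = 0
        for seed in range(20):
            config = SimulationConfig(seed=seed, n_mirnas=10, n_planted_top=0,
                                      background_target_prob=0.05)
            preds = generate_target_predictions(config, shared, ["a1"], ["b1"])
            counts = preds[preds.gene_symbol.isin(shared)].groupby("mirna_id")[
                "gene_symbol"].nunique()
            worst = max(worst, counts.max())
        assert worst <= bound

    def test_empty_gene_set_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            generate_target_predictions(small_config, [], ["a"], ["b"])


class TestGmtLibrary:
    def test_planted_term_attains_smallest_hypergeometric_p(self, small_config):
        from mirshare.enrichment import hypergeom_upper_tail

        part = planted_partition(small_config)
        pool = part["shared_symbols"]
        library = generate_gmt_library(small_config, pool)
        query = set(pool)
        pvals = {
            term: hypergeom_upper_tail(
                len(query & set(genes)), len(genes), len(query),
                small_config.n_genes_universe,
            )
            for term, genes in library.items()
        }
        assert min(pvals, key=pvals.get) == "PLANTED_TERM_01"

    def test_planted_terms_draw_from_pool(self, small_config):
        pool = set(planted_partition(small_config)["shared_symbols"])
        library = generate_gmt_library(small_config, sorted(pool))
        planted = library["PLANTED_TERM_01"]
        assert len(pool & set(planted)) / len(planted) >= 0.6

    def test_fixed_seed_gives_identical_gmt_bytes(self, small_config, tmp_path):
        paths = []
        for name in ("a.gmt", "b.gmt"):
            library = generate_gmt_library(small_config, ["GENE00001", "GENE00002"])
            write_gmt(library, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_term_size_exceeding_universe_rejected(self):
        config = SimulationConfig(seed=0, n_genes_universe=5000,
                                  term_size_range=(30, 50))
        with pytest.raises(ConfigurationError):
            generate_gmt_library(config, ["g1"], universe=["g1", "g2", "g3"])


class TestInteractome:
    def test_two_nodes_single_edge(self):
        config = SimulationConfig(seed=0, n_planted_hubs=1, pa_edges_per_node=1)
        edges = generate_interactome(config, ["x", "y"])
        assert len(edges) == 1
        assert set(edges.iloc[0][["geneA", "geneB"]]) == {"x", "y"}

    def test_simple_graph_and_confidence_range(self, small_config):
        nodes = [f"N{i}" for i in range(40)]
        edges = generate_interactome(small_config, nodes)
        assert (edges.geneA != edges.geneB).all()
        assert not edges.duplicated(["geneA", "geneB"]).any()
        assert edges.confidence.between(0, 1).all()

    def test_configuration_model_realizes_prescribed_degrees(self):
        seq = (3, 3, 2, 2, 2, 1, 1, 1, 1)
        config = SimulationConfig(seed=4, network_model="configuration",
                                  degree_sequence=seq, n_planted_hubs=2)
        edges = generate_interactome(config, [f"n{i}" for i in range(len(seq))])
        degrees = pd.concat([edges.geneA, edges.geneB]).value_counts()
        got = sorted(degrees.reindex([f"n{i}" for i in range(len(seq))], fill_value=0))
        assert got == sorted(seq)

    def test_fewer_nodes_than_hubs_rejected(self):
        config = SimulationConfig(seed=0, n_planted_hubs=5)
        with pytest.raises(ConfigurationError):
            generate_interactome(config, ["a", "b", "c"])


class TestQpcrDataset:
    def test_zero_sd_recovers_planted_fold_exactly(self):
        qpcr = QpcrConfig(
            n_control=3, n_pd=3, n_glioma=3,
            plasma_effects={"hsa-miR-16-5p": {"PD": 0.0, "glioma": math.log2(3.24)}},
            tissue_effects={}, undetectable_plasma=(),
            within_sd=0.0, reference_sd=0.0, spike_sd=0.0,
        )
        ct = generate_qpcr_dataset(SimulationConfig(seed=0, qpcr=qpcr))
        ratios = quantify_dataset(ct)
        means = ratios[ratios.analyte == "hsa-miR-16-5p"].groupby("group")["ratio"].mean()
        assert means["glioma"] / means["control"] == pytest.approx(3.24, rel=1e-3)

    def test_zero_effects_zero_sd_gives_unit_ratios(self):
        qpcr = QpcrConfig(
            n_control=2, n_pd=2, n_glioma=2,
            plasma_effects={"m1": {"PD": 0.0, "glioma": 0.0}},
            tissue_effects={"m1": 0.0}, undetectable_plasma=(),
            within_sd=0.0, reference_sd=0.0, spike_sd=0.0,
        )
        ct = generate_qpcr_dataset(SimulationConfig(seed=0, qpcr=qpcr))
        ratios = quantify_dataset(ct)
        assert ratios["ratio"].to_numpy() == pytest.approx(np.ones(len(ratios)), rel=1e-3)

    def test_undetectable_analytes_emitted_above_cutoff(self, small_config):
        ct = generate_qpcr_dataset(small_config)
        plasma = ct[ct.compartment == "plasma"]
        for analyte in small_config.qpcr.undetectable_plasma:
            assert (plasma.loc[plasma.analyte == analyte, "ct"] > 40).all()

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ConfigurationError):
            QpcrConfig(default_efficiency=2.5).validate()
        with pytest.raises(ConfigurationError):
            QpcrConfig(efficiencies={"m1": 0.9}).validate()


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_outputs(self, small_config):
        part = planted_partition(small_config)
        frames = [
            generate_target_predictions(
                small_config, part["shared_symbols"],
                part["A_only_symbols"], part["B_only_symbols"],
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(frames[0], frames[1])
        tables = [generate_qpcr_dataset(small_config) for _ in range(2)]
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_generators_use_independent_streams(self, small_config):
        """Consuming one generator does not perturb another's output."""
        a1 = generate_disease_associations(small_config)
        _ = generate_qpcr_dataset(small_config)
        a2 = generate_disease_associations(small_config)
        pd.testing.assert_frame_equal(a1, a2)
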