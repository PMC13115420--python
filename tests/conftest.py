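import pytest

from mirshare.config import QpcrConfig, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fast, small-scale simulation used by most unit tests."""
    return SimulationConfig(
        seed=5,
        n_genes_universe=400,
        disease_A_size=60,
        disease_B_size=80,
        overlap_size=30,
        n_terms_A=4,
        n_terms_B=3,
        n_mirnas=20,
        n_planted_top=2,
        n_library_terms=10,
        term_size_range=(5, 20),
        n_network_nodes=30,
        qpcr=QpcrConfig(n_control=4, n_pd=4, n_glioma=4, n_tissue=4),
    )


@pytest.fixture(scope="session")
def paper_scale_run():
    """One default ('paper-scale') generation shared across the session."""
    from mirshare.ranking import aggregate_predictions
    from mirshare.synthetic import generate_target_predictions, planted_partition

    config = SimulationConfig(seed=1)
    partition = planted_partition(config)
    predictions = generate_target_predictions(
        config,
        partition["shared_symbols"],
        partition["A_only_symbols"],
        partition["B_only_symbols"],
    )
    pairs = aggregate_predictions(predictions)
    return config, partition, predictions, pairs
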