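import pytest

from tagdge import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_noisy_experiment():
    """A small 3-library experiment with protocol noise, shared across tests."""
    config = SimConfig(
        n_genes=150,
        transcript_length_range=(300, 1200),
        depth=30_000,
        de_fraction=0.2,
        de_fold_change=4.0,
        error_rate=0.01,
        adaptor_only_rate=0.02,
        n_tag_rate=0.01,
        seed=42,
    )
    genes, libraries, truth = simulate_experiment(config)
    return config, genes, libraries, truth


@pytest.fixture(scope="session")
def clean_experiment():
    """A noise-free 2-library experiment: every raw tag is a true 3' gene tag."""
    config = SimConfig(
        n_genes=200,
        transcript_length_range=(300, 1200),
        n_libraries=2,
        depth=100_000,
        de_fraction=0.1,
        de_fold_change=4.0,
        error_rate=0.0,
        adaptor_only_rate=0.0,
        n_tag_rate=0.0,
        seed=7,
    )
    genes, libraries, truth = simulate_experiment(config)
    return config, genes, libraries, truth
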