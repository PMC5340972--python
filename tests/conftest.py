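import pytest

from immevo import synthetic as syn


@pytest.fixture(scope="session")
def small_dataset():
    """Compact three-population dataset for unit tests."""
    cfg = syn.SyntheticConfig(
        n_cells=120,
        n_genes=800,
        n_markers_per_type=20,
        n_program_genes_per_type=60,
        seed=42,
    )
    return syn.generate_expression_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-condition dataset: 300 cells, (0.65, 0.31, 0.04), 2 batches."""
    return syn.generate_expression_dataset(syn.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def toy_segments():
    return syn.generate_germline_segments(4, 3, seed=7)
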