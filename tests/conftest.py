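import numpy as np
import pytest

import proteotrans as pt


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired multi-omics dataset with ground truth (session-cached)."""
    cfg = pt.GenerativeConfig(n_samples=120, n_genes=250, n_proteins=90, seed=11)
    dataset, truth = pt.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tiny_submodel(small_dataset):
    """One trained submodel on the small dataset (session-cached)."""
    _, dataset, _ = small_dataset
    cfg = pt.SubmodelConfig(
        encoder_source="mrna", encoder_representation="pc", encoder_size=15,
        latent_dim=6, hidden_dims=(24,), max_epochs=60, patience=10,
        batch_size=32, seed=3)
    return pt.train_submodel(dataset, cfg)


def assert_matrices_equal(a, b):
    assert a.feature_ids == b.feature_ids
    assert a.sample_ids == b.sample_ids
    np.testing.assert_array_equal(a.values, b.values)
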