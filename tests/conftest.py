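import numpy as np
import pytest

from debatch import (NormalizationSpec, SyntheticConfig, generate_synthetic,
                     normalize_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """120 x 50, 3 batches, 2 QCs per batch — fast fixture for unit tests."""
    ds, truth = generate_synthetic(
        SyntheticConfig(n_samples=120, n_features=50, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    ds, truth = small_dataset
    return normalize_dataset(ds, NormalizationSpec("standard")), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
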