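import numpy as np
import pandas as pd
import pytest

from alrpls import AbundanceTable, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset shared by read-only tests."""
    cfg = SimConfig(
        n_samples_per_group=30,
        n_features=80,
        n_line_affected=10,
        n_imf_drivers=10,
        n_bodyfat_drivers=10,
        n_shared_drivers=5,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_relative():
    """Hand-sized strictly positive relative table (4 samples x 5 features)."""
    rng = np.random.default_rng(11)
    counts = rng.uniform(1, 100, size=(4, 5))
    rel = counts / counts.sum(axis=1, keepdims=True)
    return AbundanceTable(
        values=rel,
        sample_ids=[f"s{i}" for i in range(4)],
        feature_ids=[f"f{j}" for j in range(5)],
        kind="relative",
    )
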