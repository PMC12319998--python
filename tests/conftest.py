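import numpy as np
import pytest

from restfc.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(n_subjects=12, n_runs=4, n_nodes=32, n_timepoints=120, seed=11)
    timeseries, snycq, behavior, truth = generate_dataset(cfg)
    return cfg, timeseries, snycq, behavior, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
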