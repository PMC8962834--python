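import logging

import numpy as np
import pytest

from ecgorigin.synthetic import SimulationConfig, default_benchmark, simulate_dataset

logging.getLogger("ecgorigin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def benchmark_ds():
    """The frozen imbalanced 10-class benchmark dataset."""
    return simulate_dataset(default_benchmark())


@pytest.fixture(scope="session")
def small_cfg():
    """Small balanced 3-class world for fast pipeline-level tests."""
    return SimulationConfig(
        n_classes=3, class_counts=(30, 30, 30),
        patients_per_class=(5, 5, 5), record_length=700, seed=7)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
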