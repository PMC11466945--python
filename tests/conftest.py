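import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from tailnet.simulate import SimConfig, simulate_dataset, simulate_herd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240927)


@pytest.fixture(scope="session")
def small_config():
    """Three pens (one per litter-origin treatment), one period."""
    return SimConfig(n_pens=3, periods=(15,), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def study_design_dataset():
    """The full study design: 12 pens x 8 pigs x 3 periods."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simulate_herd(small_config)
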