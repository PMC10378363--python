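import numpy as np
import pytest

from ramandx.preprocess import preprocess_manifest
from ramandx.synthetic import SimConfig, generate_dataset

#: reduced study-design-like shape for fast unit tests
SMALL_KW = dict(
    n_cells={"NFC": 24, "NIH/3T3": 20, "MBM-T": 22},
    site_counts={
        "center": {"NFC": 24, "NIH/3T3": 19, "MBM-T": 21},
        "cytoplasm": {"NFC": 16, "NIH/3T3": 12, "MBM-T": 10},
        "membrane": {"NFC": 16, "NIH/3T3": 13, "MBM-T": 10},
    },
)


@pytest.fixture(scope="session")
def small_manifest():
    return generate_dataset(SimConfig(seed=42, **SMALL_KW))


@pytest.fixture(scope="session")
def small_preprocessed(small_manifest):
    return preprocess_manifest(small_manifest)


@pytest.fixture(scope="session")
def table1_manifest():
    """Full study-design shape: 169/136/152 cells, 997 spectra."""
    return generate_dataset(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
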