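import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose helpers.py

from bsamap.simulate import SimConfig, emit_dataset, simulate_f2


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation config shared by I/O and pipeline tests."""
    return SimConfig(
        n_f2=80,
        pool_size=15,
        n_sites=80,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        causal_chrom="chr2",
        causal_pos=200_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_f2(small_config)


@pytest.fixture(scope="session")
def dataset_dir(small_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    emit_dataset(small_truth, out)
    return out
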