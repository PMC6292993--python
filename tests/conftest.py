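import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from gcaa import SimParams, simulate_study
from gcaa.features import default_feature_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def feature_table():
    return default_feature_table()


@pytest.fixture(scope="session")
def small_study():
    """12 genomes spanning GC 0.30-0.70, 8 families, short genes."""
    params = SimParams(n_codons=80, n_genomes=12, n_families=8, seed=11)
    return params, simulate_study(params)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(2024)
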