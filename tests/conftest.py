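import numpy as np
import pytest

from motifcnn.motifs import MotifPool, MotifPWM, load_default_pool
from motifcnn.simulate import generate_dataset


@pytest.fixture(scope="session")
def pool() -> MotifPool:
    return load_default_pool()


@pytest.fixture(scope="session")
def tiny_dataset(pool):
    """Small shared dataset for smoke/structure tests (not for convergence)."""
    return generate_dataset(pool, n_sequences=300, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def two_col_motif() -> MotifPWM:
    return MotifPWM("toy", np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]))
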