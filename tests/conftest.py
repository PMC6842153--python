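import numpy as np
import pytest

from consensuskit import load_fixture
from consensuskit.ahp import SAATY_SCALE


@pytest.fixture(scope="session")
def fixture():
    """The packaged study tables, loaded (and validated) once per session."""
    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_reciprocal_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random Saaty-scale reciprocal matrix (test-data helper)."""
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = rng.choice(SAATY_SCALE)
            m[i, j] = v
            m[j, i] = 1.0 / v
    return m
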