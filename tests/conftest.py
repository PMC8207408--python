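import numpy as np
import pytest

from trophinet import (
    BipartiteNetwork,
    GeneratorConfig,
    InteractionRecord,
    generate_combined,
)


@pytest.fixture
def staircase3():
    """Perfectly nested 3x3 staircase."""
    return np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def two_blocks():
    """Two disjoint complete 2x2 blocks (planted 2-module network)."""
    A = np.zeros((4, 4), dtype=int)
    A[:2, :2] = 1
    A[2:, 2:] = 1
    return BipartiteNetwork([f"c{i}" for i in range(4)], [f"r{i}" for i in range(4)], A)


@pytest.fixture
def toy_records():
    """Three consumers, mixed main/secondary ranks."""
    return [
        InteractionRecord("s1", "r1", "main"),
        InteractionRecord("s1", "r2", "secondary"),
        InteractionRecord("s2", "r2", "main"),
        InteractionRecord("s3", "r1", "main"),
        InteractionRecord("s3", "r3", "secondary"),
    ]


@pytest.fixture(scope="session")
def combined_default():
    """Default-condition combined synthetic community (study-like regime)."""
    return generate_combined(GeneratorConfig(seed=42))


def random_binary_matrix(rng, n, m, fill=0.4, ensure_nonzero_rows=False):
    A = (rng.random((n, m)) < fill).astype(int)
    if ensure_nonzero_rows:
        for i in np.flatnonzero(A.sum(axis=1) == 0):
            A[i, rng.integers(m)] = 1
        for j in np.flatnonzero(A.sum(axis=0) == 0):
            A[rng.integers(n), j] = 1
    if A.sum() == 0:
        A[0, 0] = 1
    return A
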