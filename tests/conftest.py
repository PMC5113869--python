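import numpy as np
import pytest

from fragcomm import CommunityMatrix, IncidenceMatrix, load_taita_fragments


@pytest.fixture
def small_comm() -> CommunityMatrix:
    """2 species x 2 fragments toy matrix with grand total 6."""
    return CommunityMatrix(["sp1", "sp2"], ["f1", "f2"], np.array([[3, 0], [1, 2]]))


@pytest.fixture
def triplet_inc() -> IncidenceMatrix:
    """Rows A=[1,1,0], B=[0,1,1], C=[1,0,1]: every pair is a checkerboard."""
    return IncidenceMatrix(
        ["A", "B", "C"], ["f1", "f2", "f3"],
        np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]]),
    )


@pytest.fixture(scope="session")
def taita():
    """Packaged fragment metadata of the 12 study fragments."""
    return load_taita_fragments()


def random_incidence(rng: np.random.Generator, max_dim: int = 8) -> IncidenceMatrix:
    """Random binary matrix with at least two occupied rows and columns."""
    while True:
        s = rng.integers(2, max_dim + 1)
        f = rng.integers(2, max_dim + 1)
        a = (rng.random((s, f)) < rng.uniform(0.2, 0.8)).astype(int)
        if (a.sum(axis=1) > 0).sum() >= 2 and a.sum() > 0:
            return IncidenceMatrix(
                [f"s{i}" for i in range(s)], [f"f{j}" for j in range(f)], a
            )
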