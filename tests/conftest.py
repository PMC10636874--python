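import numpy as np
import pytest

from lncgo.netbuild import ComponentNetwork, EntityIndex
from lncgo.synthdata import SynthConfig, generate


@pytest.fixture
def small_index():
    return EntityIndex(["l1", "l2"], ["p1", "p2"], ["m1"])


def empty_components():
    """The six component networks, all empty."""
    return dict(
        L=ComponentNetwork("lncrna", "lncrna"),
        P=ComponentNetwork("protein", "protein"),
        M=ComponentNetwork("mirna", "mirna"),
        LP=ComponentNetwork("lncrna", "protein"),
        LM=ComponentNetwork("lncrna", "mirna"),
        PM=ComponentNetwork("protein", "mirna"),
    )


@pytest.fixture
def tiny_bundle():
    """Small planted-structure bundle for fast integration tests."""
    return generate(SynthConfig(n_l=12, n_p=24, n_m=6, g=2, p_in=0.4,
                                p_out=0.05, terms_per_group=2, seed=11))


def random_symmetric(rng: np.random.Generator, n: int, density: float = 0.5):
    """Random symmetric nonnegative matrix with zero diagonal."""
    M = rng.random((n, n)) * (rng.random((n, n)) < density)
    M = np.triu(M, k=1)
    return M + M.T


def random_connected_adjacency(rng: np.random.Generator, n: int):
    """Random weighted symmetric adjacency guaranteed connected via a path."""
    M = random_symmetric(rng, n, density=0.4)
    for i in range(n - 1):  # spanning path keeps every node reachable
        w = 0.2 + rng.random()
        M[i, i + 1] = M[i + 1, i] = max(M[i, i + 1], w)
    return M
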