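import numpy as np
import pytest

from crossnet_astm import build_grid, generate_movie


@pytest.fixture(scope="session")
def tiny_grid():
    """Smallest nondegenerate lattice: 5x5, m=3 (N=25, M=8)."""
    return build_grid(5, 5, 3)


@pytest.fixture(scope="session")
def small_grid():
    """10x10, m=5 (N=100, M=24): big enough for capacity-style checks."""
    return build_grid(10, 10, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_movie(tiny_grid):
    return generate_movie(tiny_grid, Q=6, d=0.5, seed=42)
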