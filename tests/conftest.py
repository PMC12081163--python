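import numpy as np
import pytest

from mmdepth.core import (
    depolarizer,
    linear_diattenuator,
    linear_retarder,
    rotator,
)


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """A random physically realizable Mueller matrix.

    Built as a product of elementary physical elements (rotator,
    realizable diagonal depolarizer, retarder, diattenuator); products of
    physical matrices are physical.
    """
    while True:
        a, b, c = rng.uniform(0.0, 1.0, 3)
        try:
            dep = depolarizer(a, b, c)
            break
        except Exception:
            continue
    M = (
        rotator(rng.uniform(0, 180)).m
        @ dep.m
        @ linear_retarder(rng.uniform(0, 180), rng.uniform(0, 180)).m
        @ linear_diattenuator(rng.uniform(0, 0.9), rng.uniform(0, 180)).m
    )
    return M


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_matrices(rng):
    def factory(n: int):
        return np.stack([random_physical_mueller(rng) for _ in range(n)])

    return factory
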