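import numpy as np
import pytest

import shapecat as sc


@pytest.fixture
def design_2x2():
    """Balanced 2 × 2 design with 8 stimuli per cell (32 conditions)."""
    return sc.make_design(2, 2, 8)


@pytest.fixture
def design_9x6():
    """Fully crossed 9-shape × 6-category design (54 conditions)."""
    return sc.make_design(9, 6, 1)


def random_rdm(n: int, rng: np.random.Generator, distinct: bool = False) -> sc.RDM:
    """A random symmetric zero-diagonal RDM on n labelled conditions."""
    m = n * (n - 1) // 2
    v = rng.random(m)
    if distinct:
        v = rng.permutation(m) + rng.random(m) * 0.1
    return sc.devectorize(v, [f"c{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
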