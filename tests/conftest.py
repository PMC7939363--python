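import dataclasses

import numpy as np
import pytest

from devozoo.config import SimConfig
from devozoo.core import build_initial_morphology


@pytest.fixture(scope="session")
def sheet3():
    """Standard initial morphology: rings=3 sheet (37 epithelial cells)."""
    return build_initial_morphology(3)


@pytest.fixture
def quick_sim():
    """Factory for short, seeded simulation configs."""

    def make(seed=0, **kw):
        kw.setdefault("max_steps", 150)
        return dataclasses.replace(SimConfig(), seed=seed, **kw)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(np.random.SeedSequence(12345))
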