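import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from apisa import PlantSpec, planted_expression

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expression():
    """Deterministic 4 samples x 3 genes frame with distinct values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0],
         [2.0, 4.0, 1.0],
         [5.0, 1.0, 2.0],
         [0.0, 3.0, 4.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["g1", "g2", "g3"],
    )


@pytest.fixture(scope="session")
def default_instance():
    """The canonical 5-group planted instance (m=200, n=500)."""
    return planted_expression(PlantSpec(), rng_seed=42)


@pytest.fixture(scope="session")
def small_instance():
    """A faster 3-group planted instance for end-to-end tests."""
    spec = PlantSpec(m=90, n=240, prevalences=(0.35, 0.35, 0.3),
                     genes_per_module=30, delta=3.0)
    return spec, planted_expression(spec, rng_seed=7)
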