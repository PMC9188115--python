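import numpy as np
import pytest

from hierat import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset: 3x3x3x3 tree, 6 members, 64 dims."""
    return generate(SyntheticSpec(), seed=42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small dataset for loops that scale quadratically."""
    return generate(SyntheticSpec(branching=(2, 2, 2, 2), members_per_superfam=3,
                                  dim=8), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
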