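import numpy as np
import pytest

from milrel.synthgen import make_fixture


@pytest.fixture(scope="session")
def tiny_binary():
    """20-bag binary dataset, 10 per class, reduced feature dimension."""
    return make_fixture("tiny_binary")


@pytest.fixture(scope="session")
def tiny_multiclass():
    """21-bag, 7-class subtyping dataset."""
    return make_fixture("tiny_multiclass")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
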