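import numpy as np
import pytest

from imogfold import HPSequence, parse_hp_string


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def hph():
    return parse_hp_string("HPH")


@pytest.fixture
def fig_sequence():
    """The worked 14-residue example sequence used throughout the docs."""
    return HPSequence("HHPPHPHPHPHPHP", label="example-14")
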