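import numpy as np
import pytest

from gplandscape import SequenceSpace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def binary2():
    return SequenceSpace(["01"] * 2)


@pytest.fixture
def binary3():
    return SequenceSpace(["01"] * 3)


@pytest.fixture
def acg2():
    return SequenceSpace(["ACG"] * 2)


@pytest.fixture
def dna3():
    return SequenceSpace(["ACGT"] * 3)


@pytest.fixture
def mixed_space():
    return SequenceSpace(["AC", "ACG"])
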