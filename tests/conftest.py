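import numpy as np
import pytest

from phytrim import Alignment


@pytest.fixture
def dna_aln():
    return Alignment([("a", "ACGT"), ("b", "AC-T")], "DNA")


@pytest.fixture
def ilmv_column():
    """Single amino-acid column with I, L, M, V at 25% each."""
    return Alignment([("a", "I"), ("b", "L"), ("c", "M"), ("d", "V")], "AA")


@pytest.fixture
def cqwy_column():
    """Single amino-acid column with C, Q, W, Y at 25% each."""
    return Alignment([("a", "C"), ("b", "Q"), ("c", "W"), ("d", "Y")], "AA")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
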