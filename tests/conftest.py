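import logging

import numpy as np
import pytest

from bowspace.protein import ProteinSequence, PropertyScaleTable

logging.getLogger("bowspace").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def table() -> PropertyScaleTable:
    return PropertyScaleTable.default()


@pytest.fixture(scope="session")
def random_sequences():
    """50 random canonical sequences of length 3..200 for property tests."""
    rng = np.random.default_rng(1234)
    from bowspace.protein import AMINO_ACIDS

    seqs = []
    for i in range(50):
        n = int(rng.integers(3, 201))
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        seqs.append(ProteinSequence(id=f"R{i}", residues=residues))
    return seqs


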