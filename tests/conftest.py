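import numpy as np
import pytest

from aptapred.seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, name="p"):
    return SequenceRecord(name, "".join(rng.choice(list(AA), size=length)), "protein")


def random_dna(rng, length, name="d"):
    return SequenceRecord(name, "".join(rng.choice(list("ACGT"), size=length)), "DNA")


def random_rna(rng, length, name="r"):
    return SequenceRecord(name, "".join(rng.choice(list("ACGU"), size=length)), "RNA")
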