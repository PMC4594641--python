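import numpy as np
import pytest
from hypothesis import settings

from clockdiv.io_formats import Alphabet, Msa, SequenceRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def tiny_msa():
    return Msa(
        (
            SequenceRecord("A", "MKVLR"),
            SequenceRecord("B", "MKVLR"),
            SequenceRecord("C", "MKILR"),
            SequenceRecord("D", "MRILK"),
        )
    )


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
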