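import numpy as np
import pytest

from epitopescan.core import AMINO_ACIDS, BindingRecord
from epitopescan.datasets import builtin_library


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210224)


def random_peptide(rng, k=9):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, k))


def make_record(peptide="AAAAAAAAA", pos=1, sequence_id="seq1",
                allele="HLA-DRB1*01:01", score=0.0, rank=None):
    return BindingRecord(peptide=peptide, pos=pos, sequence_id=sequence_id,
                         allele=allele, score=score, rank=rank)
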