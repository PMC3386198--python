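import numpy as np
import pytest

from paleofoam.records import Alignment, SequenceRecord

# Primer-binding sites of the coelacanth element and human foamy virus,
# used as tiny real-sequence fixtures.
PBS_COELACANTH = "TGGCACCCAACGTGGGG"
PBS_HUMAN_FV = "TGGCGCCCAACGTGGGG"


@pytest.fixture
def pbs_fasta(tmp_path):
    path = tmp_path / "pbs.fasta"
    path.write_text(
        f">CoeEFV_PBS primer binding site\n{PBS_COELACANTH}\n"
        f">HFV_PBS primer binding site\n{PBS_HUMAN_FV}\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20121)


def make_alignment(*seqs: str, ids=None) -> Alignment:
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    return Alignment([SequenceRecord(id=i, residues=s) for i, s in zip(ids, seqs)])
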