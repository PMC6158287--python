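import numpy as np
import pytest

from sortsel.readprep import ReadPair
from sortsel.variantcall import ReferenceProtein


@pytest.fixture(scope="session")
def ref():
    return ReferenceProtein.default()


def make_pair(seq1, seq2, q1=30, q2=30, pair_id="p"):
    """ReadPair with scalar or per-base qualities."""
    q1 = np.full(len(seq1), q1) if np.isscalar(q1) else np.asarray(q1)
    q2 = np.full(len(seq2), q2) if np.isscalar(q2) else np.asarray(q2)
    return ReadPair(id=pair_id, read1_seq=seq1, read1_qual=q1,
                    read2_seq=seq2, read2_qual=q2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
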