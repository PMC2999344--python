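import numpy as np
import pytest

from favat.matrices import SubstitutionMatrix, load_matrix
from favat.profile_io import make_profile
from favat.tripalign import AlignParams


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture
def default_params(blosum62):
    return AlignParams(matrix=blosum62)


def random_small_matrix(rng, alphabet="ACDE"):
    """Random symmetric integer matrix with diagonal above off-diagonal."""
    n = len(alphabet)
    off = rng.integers(-3, 3, size=(n, n))
    scores = ((off + off.T) // 2).astype(np.int64)
    np.fill_diagonal(scores, rng.integers(3, 8, size=n))
    return SubstitutionMatrix("random", alphabet, scores)


def random_profile(rng, label, alphabet="ACDE", max_len=4, max_seqs=2,
                   gap_prob=0.0):
    """Random validated profile; gap columns never all-gap."""
    n = int(rng.integers(1, max_seqs + 1))
    length = int(rng.integers(1, max_len + 1))
    symbols = list(alphabet)
    cols = []
    for _ in range(length):
        col = [
            "-" if (n > 1 and rng.random() < gap_prob)
            else symbols[rng.integers(len(symbols))]
            for _ in range(n)
        ]
        if all(c == "-" for c in col):
            col[0] = symbols[rng.integers(len(symbols))]
        cols.append(col)
    seqs = ["".join(col[a] for col in cols) for a in range(n)]
    return make_profile(seqs, label=label)


def random_align_params(rng, matrix, allow_end_free=True):
    gep = float(rng.integers(0, 3))
    gop = gep + float(rng.integers(0, 5))
    free = bool(rng.integers(0, 2)) if allow_end_free else False
    return AlignParams(matrix=matrix, gap_open=gop, gap_extend=gep,
                       end_gaps_free=free)
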