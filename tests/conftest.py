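import numpy as np
import pytest

from barcodecmp.seqdata import Sequence, SequenceSet

from tests.helpers import REF4


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def ref4_set() -> SequenceSet:
    return SequenceSet([Sequence(label=k, residues=v) for k, v in REF4.items()])


@pytest.fixture
def random_tree_pair():
    """Factory for pairs of NJ trees over the same taxa from random
    Euclidean distance matrices."""
    from barcodecmp.compdist import DistanceMatrix
    from barcodecmp.trees import nj

    def make(seed: int, n: int = 7):
        rng = np.random.default_rng(seed)
        trees = []
        labels = [f"t{i}" for i in range(n)]
        for _ in range(2):
            x = rng.random((n, 3))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            trees.append(nj(DistanceMatrix(labels=labels, values=d)))
        return trees

    return make
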