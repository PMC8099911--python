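import numpy as np
import pytest

from anchortf.geneselect import ExpressionMatrix
from anchortf.motifs import PFMModel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """8 genes x 6 samples, two time groups, no missing values."""
    values = rng.normal(8.0, 1.0, size=(8, 6))
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"s{j}" for j in range(6)],
        values=values,
        sample_time=["early"] * 3 + ["late"] * 3,
        log_scale=True,
    )


@pytest.fixture
def onehot_pfm():
    """Width-4 one-hot matrix with consensus ACGT."""
    counts = np.zeros((4, 4))
    for j, i in enumerate([0, 1, 2, 3]):
        counts[i, j] = 10
    return PFMModel(tf_name="ONEHOT", counts=counts)


def random_pfm(rng, width=6, name="RND"):
    counts = rng.integers(0, 20, size=(4, width)).astype(float)
    counts[rng.integers(0, 4, width), np.arange(width)] += 5  # no empty column
    return PFMModel(tf_name=name, counts=counts)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
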