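import numpy as np
import pytest

from lssurface.model import AlleleMatrix, GenotypeSequence, Haplotype


@pytest.fixture
def rng():
    return np.random.default_rng(20230809)


def random_haploid_instance(rng, max_L=8, max_N=4, min_L=2, min_N=2):
    L = int(rng.integers(min_L, max_L + 1))
    N = int(rng.integers(min_N, max_N + 1))
    H = AlleleMatrix(rng.integers(0, 2, size=(L, N)))
    h = Haplotype(rng.integers(0, 2, size=L))
    return h, H


def random_diploid_instance(rng, max_L=6, max_N=3, min_L=2, min_N=2):
    L = int(rng.integers(min_L, max_L + 1))
    N = int(rng.integers(min_N, max_N + 1))
    H = AlleleMatrix(rng.integers(0, 2, size=(L, N)))
    g = GenotypeSequence(rng.integers(0, 2, size=(L, 2)))
    return g, H
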