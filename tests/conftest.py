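import numpy as np
import pytest

from kernelgp import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160809)


def random_dosages(rng, n, p):
    """Random raw 0/1/2 dosage GenotypeMatrix with per-marker frequencies."""
    q = rng.uniform(0.1, 0.5, size=p)
    return GenotypeMatrix(rng.binomial(2, q, size=(n, p)).astype(float))
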