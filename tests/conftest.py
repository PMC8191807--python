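import numpy as np
import pytest

from fluctspec import synthetic_reporter


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def reporter():
    """Synthetic GC-rich reporter with its planted repeat pair and QP."""
    return synthetic_reporter(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
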