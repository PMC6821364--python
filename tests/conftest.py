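import numpy as np
import pytest

from selexpress import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def uniform_bg():
    return sim.uniform_background()


@pytest.fixture(scope="session")
def biased_bg():
    return sim.biased_background()


@pytest.fixture(scope="session")
def small_library(biased_bg):
    """20k-read background library at the default biased composition."""
    return sim.generate_background_library(biased_bg, n_reads=20_000, seed=77)


def random_reads(rng, n, lengths=(8, 19)):
    """Uniform-composition random reads with lengths in the given range."""
    out = []
    for _ in range(n):
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        out.append("".join(rng.choice(list("ACGT"), size=L)))
    return out
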