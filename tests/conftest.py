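import numpy as np
import pytest

from codonshuffle.genetic_code import standard_code
from codonshuffle.simulate import generate_random_cds


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def make_random_cds():
    """Factory for random coding sequences with Dirichlet third-position bias."""

    def _make(rng, n_codons, alpha=1.0, **kwargs):
        freqs = rng.dirichlet(np.full(4, alpha))
        return generate_random_cds(n_codons, freqs, rng, **kwargs)

    return _make
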