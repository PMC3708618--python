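import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbrealign.pb_align import PBSubstitutionMatrix
from pbrealign.pb_codec import PB_ALPHABET, PBDefinitions

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(diag=2.0, off=-1.0, special=()):
    """A full 16x16 matrix with uniform diagonal/off-diagonal values plus
    optional symmetric overrides [(letter, letter, value), ...]."""
    V = np.full((16, 16), float(off))
    np.fill_diagonal(V, float(diag))
    for x, y, v in special:
        i, j = PB_ALPHABET.index(x), PB_ALPHABET.index(y)
        V[i, j] = V[j, i] = float(v)
    return PBSubstitutionMatrix(letters=PB_ALPHABET, values=V)


@pytest.fixture(scope="session")
def defs():
    return PBDefinitions.load()


@pytest.fixture(scope="session")
def bundled_matrix():
    return PBSubstitutionMatrix.load()


@pytest.fixture
def toy_matrix():
    return make_matrix()
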