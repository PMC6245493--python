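import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from stagealign import ScoringScheme


@pytest.fixture(scope="session")
def lin112():
    """Match +1, mismatch -1, linear gap -2: the worked-example scheme."""
    return ScoringScheme.linear(1, 1, 2)


@pytest.fixture(scope="session")
def aff51():
    return ScoringScheme.affine(1, 1, 5, 1)


@pytest.fixture(scope="session")
def local_pair():
    """The printed 12-mer pair whose optimal local score is 5."""
    return "TATAGGTAGCTA", "GAGCTATGAGGT"


@pytest.fixture(scope="session")
def global_pair():
    """The printed 12-mer pair of the global DP matrix example."""
    return "ATTGTCAGGAGG", "ACTTGTCCGAGA"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
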