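import random

import pytest
from hypothesis import HealthCheck, settings

from sigdb.paillier import keygen

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def key512():
    """One 512-bit test key pair shared by the whole session."""
    return keygen(512)


@pytest.fixture(scope="session")
def fixture_rng():
    """Deterministic crypto RNG for reproducibility tests (not secure)."""
    return lambda seed=0: random.Random(seed)


def brute_kmer_positions(seq, constructor):
    """Independent oracle: set of LSH positions of a sequence's k-mers,
    via direct slicing (n-k windows) and a Python set."""
    k = constructor.k
    b = seq.bases
    return {constructor.hash_kmer(b[i : i + k]) for i in range(len(b) - k)}
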