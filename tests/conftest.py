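import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from afpkit.features import AMINO_ACIDS

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

WORKED_EXAMPLE = "MAGGDLVYAGSIAEHRKL"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """200 random valid sequences of varied length for invariant checks."""
    letters = np.array(list(AMINO_ACIDS))
    return [
        "".join(rng.choice(letters, size=rng.integers(3, 120)))
        for _ in range(200)
    ]


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">P1\nMKV\n>P2\nACD\n")
    return path
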