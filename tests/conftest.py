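import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from solscore.dataset import AminoAcidSequence

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int, sid: str = "seq") -> AminoAcidSequence:
    residues = "".join(rng.choice(list(ALPHABET), size=length))
    return AminoAcidSequence(id=sid, residues=residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
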