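import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miser.core import validate_orf
from miser.simulate import random_orf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_orf():
    """Six-codon toy ORF: ATG AAA CCC GGG TTT TGT (MKPGFC)."""
    return validate_orf("ATGAAACCCGGGTTTTGT", id="toy")


@pytest.fixture(scope="session")
def orf60():
    """Small synthetic reference, free of chemistry/scar motifs."""
    return random_orf(60, np.random.default_rng(11), id="orf60")


@pytest.fixture(scope="session")
def orf300():
    return random_orf(300, np.random.default_rng(12), id="orf300")


@pytest.fixture(scope="session")
def orf1368():
    """Full-scale synthetic target (same length as dCas9)."""
    return random_orf(1368, np.random.default_rng(13), id="orf1368")
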