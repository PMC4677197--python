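import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promotif.matrices import PFM, pfm_to_pwm
from promotif.synthetic import random_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def simple_pfm() -> PFM:
    """Length-3 motif with consensus ACG, one count per consensus base."""
    return PFM(
        motif_id="MA0001",
        name="toyTF",
        counts=[[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]],
    )


@pytest.fixture
def strong_pfm() -> PFM:
    """Informative 8-bp motif with consensus free of C (20 obs/column)."""
    consensus = "ATGATGAT"
    counts = np.full((4, 8), 0, dtype=int)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        counts[idx[b], j] = 18
        # minority observations on a non-C base to keep columns realistic
        counts[(idx[b] + 2) % 4 if (idx[b] + 2) % 4 != 1 else 3, j] += 2
    return PFM(motif_id="MA0099", name="strongTF", counts=counts)


@pytest.fixture
def small_panel():
    return random_panel(4, seed=7)


@pytest.fixture
def small_pwms(small_panel):
    return [pfm_to_pwm(p) for p in small_panel]
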