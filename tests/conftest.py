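import numpy as np
import pytest

from flockgene.model import Locus
from flockgene.simulate import PAPER_PANEL, reconstruct_paper_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def paper_cohorts():
    """Reconstructed single-locus cohorts for every published locus."""
    return {lid: reconstruct_paper_cohort(lid) for lid in PAPER_PANEL}


@pytest.fixture
def small_panel():
    return [
        Locus("locA G>A", "G", "A"),
        Locus("locB C>T", "C", "T"),
    ]


def round_half_up(x: float, nd: int = 2) -> float:
    import math

    scale = 10**nd
    return math.floor(x * scale + 0.5) / scale
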