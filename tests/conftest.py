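import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from cohnet import synthetic as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def atlas():
    return sd.default_roi_atlas()


@pytest.fixture
def small_design():
    """Two extreme levels, one trial, three subjects: the smallest design
    that still exercises subject pooling and level contrasts."""
    return sd.ExperimentDesign(n_subjects=3,
                               levels=("extremely_light", "extremely_hard"),
                               n_trials=1)


def shared_component_spec(noise_sd: float, n_roi: int = 2,
                          band=(8.0, 13.0)) -> sd.CouplingSpec:
    """Two ROIs sharing one unit-weight band-limited component."""
    comp = sd.Component(band, tuple(range(min(2, n_roi))), (1.0, 1.0))
    return sd.CouplingSpec(n_roi, (comp,),
                           tuple(noise_sd for _ in range(n_roi)))
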