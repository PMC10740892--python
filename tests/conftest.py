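import numpy as np
import pytest

from vestibsim.afferents import Kinetics, MembraneModel
from vestibsim.anatomy import build_default_labyrinth
from vestibsim.fields import Medium
from vestibsim.stimgen import PulseShape, WaveformSpec


@pytest.fixture(scope="session")
def tissue():
    return Medium.tissue()


@pytest.fixture(scope="session")
def hh_model():
    return MembraneModel()


@pytest.fixture(scope="session")
def surrogate_model():
    return MembraneModel(kinetics=Kinetics.THRESHOLD_SURROGATE)


@pytest.fixture(scope="session")
def rect200():
    return WaveformSpec(shape=PulseShape.RECT, phase_us=200.0, amp_uA=240.0)


@pytest.fixture(scope="session")
def anatomy9():
    """Small labyrinth for per-fiber cable-tier tests."""
    return build_default_labyrinth(n_per_crista=9, seed=0)


@pytest.fixture(scope="session")
def anatomy30():
    """Mid-size labyrinth for population-level cable-tier tests."""
    return build_default_labyrinth(n_per_crista=30, seed=0)
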