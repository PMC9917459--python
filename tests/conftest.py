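import numpy as np
import pytest

from gluquant import GroundTruth, StimulusProtocol


@pytest.fixture
def study_gt() -> GroundTruth:
    """Ground truth at the study conditions (N=5, q=0.09, 3 Ca levels)."""
    return GroundTruth(seed=0)


@pytest.fixture
def study_protocol() -> StimulusProtocol:
    """Three conditions x 10 trains x 5 stimuli at 5 Hz, 25-Hz imaging."""
    return StimulusProtocol()


@pytest.fixture
def single_condition_protocol() -> StimulusProtocol:
    return StimulusProtocol(conditions=("2",))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
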