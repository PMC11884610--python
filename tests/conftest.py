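import numpy as np
import pytest

from deepsm.optics import OpticalModel, ParticleState


@pytest.fixture(scope="session")
def optical():
    return OpticalModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def centered_particle():
    return ParticleState(x=32.0, y=32.0, amplitude=0.1, phase=0.0)
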