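import numpy as np
import pytest

from retmea.core import SpikeTrain, StimulusProtocol
from retmea.synth import make_protocol


@pytest.fixture
def flash_protocol():
    """One 2-s flash at the reference intensity, running 5-7 s."""
    return make_protocol("flash_series", [95.23])


@pytest.fixture
def flash_epoch(flash_protocol):
    return flash_protocol.flash_epochs()[0]


@pytest.fixture
def regular_train():
    """10-Hz clockwork spike train over 10 s."""
    return SpikeTrain("u_reg", 1, np.arange(0.05, 10.0, 0.1))


def poisson_train(rate, duration, seed, unit_id="u_poiss", electrode_id=1):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return SpikeTrain(unit_id, electrode_id, np.sort(rng.uniform(0, duration, n)))


@pytest.fixture
def dark_protocol():
    """Stimulus-free protocol: 20 s of darkness."""
    return StimulusProtocol((), 20.0)
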