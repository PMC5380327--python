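"""Shared fixtures: simulated pulling data reused across test modules."""

import numpy as np
import pytest

from sawtooth import presets
from sawtooth.simulate import NoiseModel, PullingProtocol, simulate_pull

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def protocol():
    return PullingProtocol()  # 1 um/s, 1 um ramp, k_c = 0.15 N/m


@pytest.fixture(scope="session")
def rii8_batch(protocol):
    """200 simulated MpAFP RII octamer pulls at 1 um/s, default noise."""
    streams = np.random.SeedSequence(20260921).spawn(200)
    noise = NoiseModel()
    return [
        simulate_pull(presets.rii8(), protocol, noise, np.random.default_rng(s))
        for s in streams
    ]


@pytest.fixture(scope="session")
def quiet_noise():
    """No noise, no adhesion, unbreakable tether."""
    return NoiseModel.quiet()
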