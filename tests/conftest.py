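import numpy as np
import pytest

from imfishctc.io import ChannelImage, ChannelRole, ChannelStack
from imfishctc.synthetic import SimulationParams, simulate_field


@pytest.fixture(scope="session")
def easy_field():
    """One noise-free simulated field with its ground truth."""
    return simulate_field(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def noisy_field():
    return simulate_field(SimulationParams(seed=11, noise_sigma=8.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_stack(field_id="f", **arrays) -> ChannelStack:
    """Build a ChannelStack from uint8 arrays keyed by role name."""
    channels = {
        ChannelRole(role): ChannelImage(
            pixels=np.asarray(a, dtype=np.uint8), bit_depth=8, role=ChannelRole(role)
        )
        for role, a in arrays.items()
    }
    return ChannelStack(field_id=field_id, channels=channels)
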