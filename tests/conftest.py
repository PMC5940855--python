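import numpy as np
import pytest

from spherodyn import generate_time_lapse, preset


def disk_mask(shape, center, radius):
    """Strict rasterization: pixel centers with squared distance <= r^2."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2.0 + (cc - center[1]) ** 2.0 <= radius**2


@pytest.fixture(scope="session")
def clean_leader():
    """Noise-free, single-plane leader recording with exact truth."""
    params = preset("leader", noise_sd=0.0, n_z=1, bleach_rate=0.0)
    stack, truth = generate_time_lapse(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def noisy_leader():
    """Leader preset under its default (moderate-noise, 5-plane) conditions."""
    params = preset("leader")
    stack, truth = generate_time_lapse(params)
    return params, stack, truth
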