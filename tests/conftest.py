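import numpy as np
import pytest

from corogrow import (
    PhantomConfig,
    apply_window,
    generate_phantom,
    straight_tube_phantom,
    vesselness_multiscale,
)


@pytest.fixture(scope="session")
def demo_phantom():
    """The default aorta + coronary-tree phantom (noise sd 10 HU)."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def tube():
    """Noiseless straight tube of radius 2 along x."""
    return straight_tube_phantom(shape=(40, 40, 48), radius=2.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def tube_enhanced(tube):
    return apply_window(tube.volume)


@pytest.fixture(scope="session")
def tube_vesselness(tube_enhanced):
    return vesselness_multiscale(tube_enhanced)


@pytest.fixture(scope="session")
def phantom_enhanced(noiseless_phantom):
    return apply_window(noiseless_phantom.volume)


@pytest.fixture(scope="session")
def phantom_vesselness(phantom_enhanced):
    return vesselness_multiscale(phantom_enhanced)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
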