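import numpy as np
import pytest

from udmc import PhantomSpec, generate_phantom_sequence


@pytest.fixture(scope="session")
def bounce_phantom():
    """Small remeshed bouncing phantom shared by read-only tests."""
    spec = PhantomSpec(resolution=800, n_frames=5, motion="bounce_swing", remesh=True, seed=3)
    return generate_phantom_sequence(spec)


@pytest.fixture(scope="session")
def tps_phantom():
    """Phantom whose dense motion is exactly the landmark-TPS field."""
    spec = PhantomSpec(resolution=900, n_frames=5, motion="tps_from_landmarks", seed=5)
    return generate_phantom_sequence(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
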