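import numpy as np
import pytest

from pelvifrac import phantoms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def intact_slice():
    """One noise-carrying slice with two intact bones."""
    return phantoms.render_phantom(phantoms.make_slice_spec(101, fractured=False))


@pytest.fixture(scope="session")
def fractured_slice():
    """One slice whose larger bone carries a fully severing gap."""
    return phantoms.render_phantom(phantoms.make_slice_spec(202, fractured=True))


@pytest.fixture(scope="session")
def clean_ring_spec():
    """Single noise-free elliptical bone, no artifacts."""
    return phantoms.PhantomSpec(
        image_height=256,
        image_width=256,
        bones=(
            phantoms.BoneSpec(
                center=(128.0, 128.0),
                radius=60.0,
                thickness=6.0,
                intensity=0.9,
                axis_ratio=0.85,
            ),
        ),
        noise_sigma=0.0,
        artifact_count=0,
        seed=5,
    )
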