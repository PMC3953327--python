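import numpy as np
import pytest


def make_ring(shape, center, radius, thickness=1.0):
    """Binary ring (annulus) mask."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return np.abs(d - radius) < thickness


@pytest.fixture
def ring_map():
    return make_ring((21, 21), (10, 10), 6)


@pytest.fixture
def two_cell_phantom():
    from sarsamend.synthetic import PhantomSpec, generate_phantom

    return generate_phantom(
        PhantomSpec(shape=(256, 256), n_cells=2, noise_sigma=0.0, clutter_density=0.0, seed=5)
    )
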