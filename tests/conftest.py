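import numpy as np
import pytest

from cortexforge import (REFERENCE_PARAMETERS, PillarGeometry, RenderSpec,
                         render_pillar_ring)


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_PARAMETERS


@pytest.fixture(scope="session")
def geom():
    """Fixture pillar geometry: stiffness close to the 35 pN/µm pillars."""
    return PillarGeometry(L=15.0, d=2.0, E_kPa=57.0)


@pytest.fixture(scope="session")
def small_render():
    """A coarse, fast 3-pillar render with known forces and its truth."""
    spec = RenderSpec(seed=7, n_pillars=3, ring_diameter=18.0,
                      forces=(80.0, 126.0, 160.0),
                      voxel_size=(1.0, 0.25, 0.25))
    before, after, truth = render_pillar_ring(spec)
    return spec, before, after, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
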