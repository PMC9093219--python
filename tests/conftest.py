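import numpy as np
import pytest

from cbctrec import (ConeBeamGeometry, RunConfig, SiddonProjector, Volume,
                     VolumeGrid, default_demo_config, forward_project,
                     make_phantom, default_head_phantom, run_comparison,
                     simulate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_setup():
    """16^3 grid, 4 views, detector comfortably covering the volume."""
    grid = VolumeGrid((16, 16, 16))
    geom = ConeBeamGeometry.circular(
        n_views=4, detector_shape=(24, 24), detector_pixel=(5.0, 5.0))
    return geom, grid


@pytest.fixture(scope="session")
def small_projector(small_setup):
    geom, grid = small_setup
    return SiddonProjector(geom, grid)


@pytest.fixture(scope="session")
def small_phantom_data():
    """Noiseless 16-view scan of a 24^3 head phantom (fast end-to-end
    fixture for the iterative solvers)."""
    grid = VolumeGrid((24, 24, 24))
    geom = ConeBeamGeometry.circular(
        n_views=16, detector_shape=(48, 48), detector_pixel=(2.0, 2.0))
    truth = make_phantom(default_head_phantom(grid), grid)
    projections = forward_project(truth, geom)
    return truth, projections, geom, grid


@pytest.fixture(scope="session")
def demo_comparison():
    """The full shipped comparison experiment: noiseless 64^3 head phantom,
    32 equispaced views, all five algorithms at the matched default budget.
    Session-scoped: the experiment runs once for the whole suite."""
    return run_comparison(default_demo_config(seed=1))
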