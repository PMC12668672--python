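import numpy as np
import pytest

from subtract import (
    BundleSpec,
    TrackingParams,
    VoxelGrid,
    make_protocol_for_bundle,
    make_scene,
    normalise,
    track_protocol,
)


@pytest.fixture(scope="session")
def tube_scene():
    """Zero-dispersion straight tube along +x on a 32^3 1 mm grid."""
    grid = VoxelGrid.isotropic((32, 32, 32), 1.0)
    spec = BundleSpec.straight("tube", (3.0, 16.0, 16.0), (28.0, 16.0, 16.0), radius=2.0)
    return make_scene([spec], grid)


@pytest.fixture(scope="session")
def tube_protocol(tube_scene):
    return make_protocol_for_bundle(tube_scene, "tube")


@pytest.fixture(scope="session")
def fast_params():
    return TrackingParams(streamlines_per_seed_voxel=20, rng_seed=0)


@pytest.fixture(scope="session")
def tube_distribution(tube_scene, tube_protocol, fast_params):
    return normalise(track_protocol(tube_scene.field, tube_protocol, fast_params))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
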