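import numpy as np
import pytest

from octvessel import phantom
from octvessel.phantom import VesselSegment


@pytest.fixture(scope="session")
def y_fixture():
    """A rasterized 'Y': stem splitting into two arms at one junction."""
    segs = phantom.make_y_segments(
        center=(32.0, 32.0, 16.0), stem_length=25.0, arm_length=22.0, radius=2.5
    )
    mask = phantom.rasterize(segs, (64, 64, 32), (1.0, 1.0, 1.0))
    truth_length = sum(s.length_um for s in segs)
    return segs, mask, truth_length


@pytest.fixture(scope="session")
def cylinder_mask():
    """A radius-5 capsule spanning the full x extent of a 64x64x32 grid."""
    seg = [VesselSegment((0.0, 32.0, 16.0), (64.0, 32.0, 16.0), 5.0)]
    return phantom.rasterize(seg, (64, 64, 32), (1.0, 1.0, 1.0))


def tube_network_spec(seed, **overrides):
    """Planar tube-network generator settings used across recovery tests:
    radius >= 2 voxels, >= 10-voxel branch separation, in-plane growth."""
    from octvessel import VesselNetworkSpec

    kwargs = dict(
        seed=seed,
        grid_shape=(80, 80, 40),
        voxel_spacing=(1.0, 1.0, 1.0),
        n_seed_vessels=2,
        branching_prob=0.5,
        radius_range_um=(2.0, 2.6),
        radius_decay=1.0,
        min_branch_separation_um=10.0,
        segment_length_range_um=(24.0, 40.0),
        max_generations=3,
        max_segments=30,
        branch_angle_deg=(55.0, 100.0),
        direction_jitter_deg=6.0,
        z_direction_scale=0.0,
    )
    kwargs.update(overrides)
    return VesselNetworkSpec(**kwargs)


def random_blob_mask(rng, shape=(30, 30, 30), keep=0.28):
    """Smoothed-noise random mask with nontrivial topology."""
    from scipy import ndimage

    x = ndimage.gaussian_filter(rng.random(shape), 2.0)
    return x > np.quantile(x, 1.0 - keep)
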