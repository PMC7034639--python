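import numpy as np
import pytest

from petquant import build_phantom, default_phantom_spec
from petquant.io import FrameSchedule
from petquant.phantom import PlasmaInputParams, RegionKinetics, SubjectMeta, PhantomSpec


@pytest.fixture(scope="session")
def default_noiseless():
    """Calibrated default subject, noise-free: (spec, image, labels, meta, gt)."""
    spec = default_phantom_spec(seed=7, noise_level=0.0)
    image, labels, meta, gt = build_phantom(spec)
    return spec, image, labels, meta, gt


@pytest.fixture()
def tiny_spec():
    """A 16-cube two-region phantom for fast IO and error-path tests."""
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        voxel_size=(1.0, 1.0, 1.0),
        region_geometry={
            "left": {"shape": "sphere", "center": (5, 8, 8), "radius": 3},
            "right": {"shape": "sphere", "center": (11, 8, 8), "radius": 2},
        },
        region_kinetics={
            "left": RegionKinetics("left", K1=0.2, k2=0.2),
            "right": RegionKinetics("right", K1=0.1, k2=0.4),
        },
        input=PlasmaInputParams((1.0, -1.0), (0.3, 3.0), delay=0.0),
        frames=FrameSchedule.uniform(6, 2.0),
        noise_level=0.0,
        seed=3,
        subject=SubjectMeta("T01", injected_dose=350.0, body_weight=420.0),
        tumor_regions=("left",),
    )


@pytest.fixture()
def mono_exp_input():
    """Single-exponential plasma input, convenient for closed-form checks."""
    return PlasmaInputParams((1.0,), (0.1,), delay=0.0)
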