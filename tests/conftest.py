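import numpy as np
import pytest

from microreg.barcode import default_pattern
from microreg.experiments import StudyConditions
from microreg.geometry import PlaneDecomposition
from microreg.phantom import Phantom, PhantomConfig


@pytest.fixture(scope="session")
def pattern():
    return default_pattern()


@pytest.fixture(scope="session")
def conditions():
    return StudyConditions()


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick-to-rasterize phantom with known structure."""
    cfg = PhantomConfig(
        extent=(400.0, 400.0, 400.0),
        voxel_size=2.0,
        surface_depth_mean=120.0,
        surface_amplitude=30.0,
        surface_period=200.0,
        epidermis_thickness_mean=60.0,
        bead_count=10,
        follicle_count=4,
        chunk_count=8,
        seed=7,
    )
    return Phantom(cfg)


@pytest.fixture(scope="session")
def study_phantom():
    """Full-size phantom matching the Monte-Carlo study conditions."""
    return Phantom(PhantomConfig(), seed=42)


def random_decomposition(rng, yaw_range=(np.pi / 4.5, np.pi / 3.3),
                         tilt_max=np.deg2rad(5.0), scales=(0.8, 1.0),
                         translation=(-50.0, -50.0, 0.0)):
    """Random section-cut parameters in the study geometry."""
    return PlaneDecomposition(
        angles=np.array([
            rng.uniform(*yaw_range),
            rng.uniform(-tilt_max, tilt_max),
            rng.uniform(-tilt_max, tilt_max),
        ]),
        scales=rng.uniform(*scales, size=3),
        translation=np.asarray(translation, float),
    )
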