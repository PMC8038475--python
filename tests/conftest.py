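import numpy as np
import pytest

from fringeftp import (
    CameraModel,
    GridSpec,
    OpticalSetup,
    PhotometricScene,
    ProjectionGeometry,
    make_spherical_cap,
)


@pytest.fixture(scope="session")
def small_setup() -> OpticalSetup:
    """Reduced laser spot for fast unit-level chain runs."""
    return OpticalSetup(illum_diameter=1.0)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    # 1024^2 at d/8 sampling: every chain step stays in its valid regime
    return GridSpec(n=1024, pitch=0.02 / 8.0)


@pytest.fixture(scope="session")
def geom() -> ProjectionGeometry:
    return ProjectionGeometry(L=1000.0, D=300.0, f0=1.0)


@pytest.fixture(scope="session")
def cap_surface():
    return make_spherical_cap(base_radius=40.0, cap_height=10.0, pitch=0.25)


@pytest.fixture()
def clean_scene() -> PhotometricScene:
    """Direct reflection only: no subsurface scatter, no background."""
    return PhotometricScene(direct_albedo=0.5, scatter_fraction=0.0,
                            background_illuminance=0.0)


@pytest.fixture()
def noiseless_camera() -> CameraModel:
    return CameraModel(photon_fullwell=None, read_noise=0.0)


def normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
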