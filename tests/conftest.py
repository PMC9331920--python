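import numpy as np
import pytest

from cabscan import PointCloud, PipelineConfig
from cabscan.synthcab import DefectSpec, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_grid():
    """40x40 unit-spaced (mm) grid in the z=0 plane."""
    xx, yy = np.meshgrid(np.arange(40) * 1e-3, np.arange(40) * 1e-3)
    pts = np.stack([xx.ravel(), yy.ravel(), np.zeros(1600)], axis=1)
    return PointCloud(points=pts, source="flat-grid")


@pytest.fixture
def sphere_patch():
    """Dense patch of a sphere of radius 0.05 m around its +z pole."""
    g = np.random.default_rng(7)
    R = 0.05
    n = 4000
    # directions within ~35 degrees of +z
    v = g.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 2] = np.abs(v[:, 2])
    v = v[v[:, 2] > 0.82]
    return PointCloud(points=R * v, source="sphere-R0.05"), R


@pytest.fixture(scope="session")
def dent_scene():
    spec = SceneSpec(
        seed=42,
        defects=(DefectSpec(kind="dent", center_uv=(0.8, 0.6), radius_mm=10.0, depth_mm=10.0),),
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def crack_scene():
    spec = SceneSpec(
        seed=43,
        defects=(
            DefectSpec(
                kind="crack", center_uv=(2.0, 0.5), length_mm=40.0, width_mm=4.0,
                depth_mm=10.0, orientation_rad=0.9,
            ),
        ),
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def intact_scene():
    return generate_scene(SceneSpec(seed=44))


@pytest.fixture(scope="session")
def analyzed_dent(dent_scene):
    """Dent scene run through the preprocessing chain, with transferred labels."""
    from scipy.spatial import cKDTree

    from cabscan.pipeline import preprocess_cloud

    cloud, _, _ = preprocess_cloud(dent_scene.cloud, PipelineConfig())
    tree = cKDTree(dent_scene.cloud.points)
    _, nearest = tree.query(cloud.points, k=1)
    return cloud, dent_scene.labels[nearest]
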