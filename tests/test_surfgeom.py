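"""Neighbourhood geometry: k-NN, covariance curvature, quadric fit, shape S."""

import numpy as np
import pytest

from cabscan import (
    PointCloud,
    covariance_geometry,
    curvature_field,
    feature_points,
    fit_quadric,
    knn_neighborhood,
    shape_parameter,
)
from cabscan.surfgeom import DegenerateFitError

from oracles import feature_points_brute, knn_brute


# ---------------------------------------------------------------------------
# knn_neighborhood

def test_knn_collinear():
    cloud = PointCloud(points=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    np.testing.assert_array_equal(knn_neighborhood(cloud, 0, 2), [1, 2])


def test_knn_duplicates_tie_break_lower_index():
    pts = [[0, 0, 0], [5, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]]
    cloud = PointCloud(points=pts)
    # the three duplicates at x=1 come first, lowest index first
    np.testing.assert_array_equal(knn_neighborhood(cloud, 0, 4), [2, 3, 4, 5])
    np.testing.assert_array_equal(knn_neighborhood(cloud, 0, 2), [2, 3])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_knn_matches_exhaustive_sort(seed):
    g = np.random.default_rng(seed)
    pts = g.uniform(size=(500, 3))
    cloud = PointCloud(points=pts)
    for i in [0, 17, 250, 499]:
        np.testing.assert_array_equal(
            knn_neighborhood(cloud, i, 30), knn_brute(pts, i, 30)
        )


def test_knn_k_too_large():
    with pytest.raises(ValueError):
        knn_neighborhood(PointCloud(points=np.zeros((5, 3))), 0, 5)


# ---------------------------------------------------------------------------
# covariance_geometry

def test_coplanar_neighborhood_flat(flat_grid):
    geom = covariance_geometry(flat_grid, 820, k=24)
    assert geom.eigenvalues[0] == pytest.approx(0.0, abs=1e-15)
    assert geom.kappa == pytest.approx(0.0, abs=1e-12)
    assert abs(geom.normal[2]) == pytest.approx(1.0)
    assert np.linalg.norm(geom.normal) == pytest.approx(1.0)


def test_isotropic_neighborhood_maximal_kappa():
    # cube corners have an isotropic covariance; kappa reaches its 1/3 bound
    corners = np.array(
        [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)], dtype=float
    )
    cloud = PointCloud(points=np.vstack([[[0, 0, 0]], corners]))
    geom = covariance_geometry(cloud, 0, k=8)
    assert geom.kappa == pytest.approx(1.0 / 3.0, abs=1e-9)
    assert np.all(np.diff(geom.eigenvalues) >= 0)


def test_sphere_normals_point_radially(sphere_patch):
    cloud, R = sphere_patch
    g = np.random.default_rng(3)
    viewpoint = np.array([0.0, 0.0, 10.0])
    for i in g.choice(len(cloud), 25, replace=False):
        geom = covariance_geometry(cloud, int(i), k=50, viewpoint=viewpoint)
        radial = cloud.points[i] / np.linalg.norm(cloud.points[i])
        angle = np.degrees(np.arccos(np.clip(geom.normal @ radial, -1, 1)))
        assert angle < 5.0


def test_all_coincident_kappa_zero():
    cloud = PointCloud(points=np.zeros((6, 3)))
    geom = covariance_geometry(cloud, 0, k=4)
    assert geom.kappa == 0.0


# ---------------------------------------------------------------------------
# fit_quadric

def test_quadric_exact_parabolic_cylinder():
    # z = x^2 sampled on an exactly symmetric grid, so the neighbourhood
    # covariance is exactly diagonal and the local frame coincides with the
    # world axes (x-spread > y-spread pins the tangent axes; a viewpoint
    # below the surface makes world +z the frame's +z)
    gx, gy = np.meshgrid(np.linspace(-0.15, 0.15, 9), np.linspace(-0.05, 0.05, 7))
    pts = np.stack([gx.ravel(), gy.ravel(), gx.ravel() ** 2], axis=1)
    center = int(np.flatnonzero((pts[:, 0] == 0) & (pts[:, 1] == 0))[0])
    cloud = PointCloud(points=pts)
    q = fit_quadric(cloud, center, k=62, viewpoint=[0.0, 0.0, -5.0])
    assert q.a == pytest.approx(1.0, abs=1e-8)
    assert q.b == pytest.approx(0.0, abs=1e-8)
    assert q.c == pytest.approx(0.0, abs=1e-8)
    assert (q.k1, q.k2) == (pytest.approx(2.0, abs=1e-8), pytest.approx(0.0, abs=1e-8))


def test_quadric_plane_is_zero(flat_grid):
    q = fit_quadric(flat_grid, 820, k=30)
    for v in (q.a, q.b, q.c, q.k1, q.k2):
        assert v == pytest.approx(0.0, abs=1e-9)
    assert q.shape_S == 0.5


def test_quadric_sphere_curvatures(sphere_patch):
    cloud, R = sphere_patch
    g = np.random.default_rng(5)
    # interior points only: the open rim of the patch has one-sided
    # neighbourhoods where no local fit is meaningful; individual random
    # samples scatter a few percent, so the 10% check applies to the mean
    interior = np.flatnonzero(cloud.points[:, 2] > 0.93 * R)
    k1s, k2s = [], []
    for i in g.choice(interior, 25, replace=False):
        q = fit_quadric(cloud, int(i), k=60)
        k1s.append(q.k1)
        k2s.append(q.k2)
    assert np.mean(k1s) == pytest.approx(1.0 / R, rel=0.10)
    assert np.mean(k2s) == pytest.approx(1.0 / R, rel=0.10)
    assert min(k2s) > 0.5 / R and max(k1s) < 1.5 / R


def test_quadric_second_fundamental_form_identities():
    g = np.random.default_rng(6)
    pts = g.uniform(-0.02, 0.02, (200, 3)) * [1, 1, 0.2]
    cloud = PointCloud(points=pts)
    for i in range(0, 200, 23):
        q = fit_quadric(cloud, i, k=40)
        assert q.k1 + q.k2 == pytest.approx(2 * (q.a + q.c), abs=1e-9)
        assert q.k1 * q.k2 == pytest.approx(4 * q.a * q.c - q.b**2, abs=1e-9)
        assert q.k1 >= q.k2


def test_quadric_degenerate_collinear():
    pts = np.stack([np.linspace(0, 1, 12), np.zeros(12), np.zeros(12)], axis=1)
    with pytest.raises((DegenerateFitError, ValueError)):
        fit_quadric(PointCloud(points=pts), 0, k=8)


# ---------------------------------------------------------------------------
# shape_parameter

def test_shape_parameter_analytic_values():
    assert shape_parameter(3.0, -3.0) == pytest.approx(0.5)      # symmetric saddle
    assert shape_parameter(5.0, 0.0) == pytest.approx(0.25)      # parabolic ridge
    assert shape_parameter(20.0, 20.0) == 0.0                    # convex umbilic
    assert shape_parameter(-20.0, -20.0) == 1.0                  # concave umbilic
    assert shape_parameter(0.0, 0.0) == 0.5                      # flat


def test_shape_parameter_invariances():
    g = np.random.default_rng(7)
    for _ in range(50):
        k1, k2 = sorted(g.uniform(-30, 30, 2), reverse=True)
        s = shape_parameter(k1, k2)
        assert 0.0 <= s <= 1.0
        assert shape_parameter(k2, k1) == pytest.approx(s)       # order-free
        for alpha in (0.5, 3.0, 117.0):
            assert shape_parameter(alpha * k1, alpha * k2) == pytest.approx(s)


# ---------------------------------------------------------------------------
# curvature_field / feature_points

def test_flat_grid_field(flat_grid):
    field = curvature_field(flat_grid, k=24)
    interior = ~field["boundary"].to_numpy()
    assert (field["kappa"].to_numpy()[interior] < 1e-6).all()
    s = field.loc[field["s_defined"], "S"]
    assert (np.abs(s - 0.5) < 1e-6).all()


def test_sphere_patch_field_convex(sphere_patch, flat_grid):
    cloud, R = sphere_patch
    field = curvature_field(cloud, k=50)
    flat = curvature_field(flat_grid, k=50)
    # convex umbilic: the arctan limit sends S to 0 over most of the patch
    assert field["S"].median() == pytest.approx(0.0, abs=0.05)
    assert field["kappa"].median() > flat["kappa"].median()


def test_kappa_rigid_motion_invariant(sphere_patch):
    cloud, _ = sphere_patch
    sub = PointCloud(points=cloud.points[:800])
    field = curvature_field(sub, k=30)
    g = np.random.default_rng(9)
    a, b, c = g.uniform(0, 2 * np.pi, 3)
    Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, np.cos(b), -np.sin(b)], [0, np.sin(b), np.cos(b)]])
    t = g.uniform(-1, 1, 3)
    moved = PointCloud(points=(sub.points @ (Rz @ Rx).T) + t)
    field2 = curvature_field(moved, k=30)
    np.testing.assert_allclose(
        field2["kappa"].to_numpy(), field["kappa"].to_numpy(), atol=1e-9
    )


def test_feature_points_constant_field_empty(flat_grid):
    field = curvature_field(flat_grid, k=24)
    # on the flat grid S is constant at 0.5 wherever defined
    assert len(feature_points(field, flat_grid, k=24)) == 0


def test_feature_points_single_maximum():
    g = np.random.default_rng(10)
    pts = g.uniform(size=(80, 3))
    import pandas as pd

    s = np.full(80, 0.3)
    s[17] = 0.9
    field = pd.DataFrame({"S": s, "s_defined": np.ones(80, dtype=bool)})
    got = feature_points(field, PointCloud(points=pts), k=79)
    np.testing.assert_array_equal(got, [17])


@pytest.mark.parametrize("seed", [0, 1])
def test_feature_points_match_brute_force(seed):
    import pandas as pd

    g = np.random.default_rng(seed)
    pts = g.uniform(size=(300, 3))
    s = g.uniform(size=300)
    defined = g.uniform(size=300) > 0.1
    s_nan = np.where(defined, s, np.nan)
    field = pd.DataFrame({"S": s_nan, "s_defined": defined})
    got = feature_points(field, PointCloud(points=pts), k=10)
    want = feature_points_brute(pts, s_nan, defined, 10)
    np.testing.assert_array_equal(got, want)
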