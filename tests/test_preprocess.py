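"""Statistical filtering, Euclidean clustering, ROI selection, voxel grid."""

import numpy as np
import pytest

from cabscan import (
    AxisStats,
    ClusterParams,
    PointCloud,
    StatFilterParams,
    VoxelParams,
    axis_distribution_stats,
    euclidean_cluster,
    select_roi,
    statistical_filter,
    voxel_downsample,
)
from cabscan.cloudio import EmptyCloudError

from oracles import clusters_brute, statistical_filter_brute


# ---------------------------------------------------------------------------
# statistical_filter

def test_filter_degenerate_band_keeps_all():
    # equilateral triangle: every per-point mean distance is equal, sigma = 0
    tri = PointCloud(points=[[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    out, removed = statistical_filter(tri, StatFilterParams(neighbor_count=2))
    assert len(out) == 3 and len(removed) == 0


def test_filter_removes_far_outlier():
    xx, yy = np.meshgrid(np.arange(5.0), np.arange(5.0))
    pts = np.stack([xx.ravel(), yy.ravel(), np.zeros(25)], axis=1)
    pts = np.vstack([pts, [[100.0, 0.0, 0.0]]])
    cloud = PointCloud(points=pts)
    params = StatFilterParams(neighbor_count=5, sigma_mult=1.0)
    _, removed = statistical_filter(cloud, params)
    _, removed_oracle = statistical_filter_brute(pts, 5, 1.0)
    assert 25 in removed
    np.testing.assert_array_equal(np.sort(removed), np.sort(removed_oracle))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_filter_matches_brute_force(seed):
    g = np.random.default_rng(seed)
    pts = g.normal(size=(120, 3)) * [0.05, 0.05, 0.01]
    cloud = PointCloud(points=pts)
    params = StatFilterParams(neighbor_count=8, sigma_mult=1.0)
    out, removed = statistical_filter(cloud, params)
    kept_oracle, removed_oracle = statistical_filter_brute(pts, 8, 1.0)
    np.testing.assert_array_equal(removed, removed_oracle)
    np.testing.assert_allclose(out.points, pts[kept_oracle])


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_refiltering_removes_no_more_than_first_pass(seed):
    # in the filter's outlier-removal regime (dense blob + sparse far
    # outliers, wide band) a second pass with identical parameters removes
    # fewer points; with a 1-sigma band every pass trims ~16% of any
    # continuous distribution, so no such monotonicity exists there
    g = np.random.default_rng(seed)
    blob = g.normal(scale=5e-3, size=(300, 3))
    outliers = g.uniform(-0.5, 0.5, (8, 3))
    cloud = PointCloud(points=np.vstack([blob, outliers]))
    params = StatFilterParams(neighbor_count=30, sigma_mult=3.0)
    once, removed1 = statistical_filter(cloud, params)
    _, removed2 = statistical_filter(once, params)
    assert len(removed2) <= len(removed1)


def test_filter_too_few_points():
    with pytest.raises(ValueError):
        statistical_filter(
            PointCloud(points=np.zeros((3, 3))), StatFilterParams(neighbor_count=5)
        )


# ---------------------------------------------------------------------------
# euclidean_cluster / select_roi

def test_two_separated_blobs():
    g = np.random.default_rng(0)
    a = g.normal(scale=1e-3, size=(50, 3))
    b = g.normal(scale=1e-3, size=(50, 3)) + [1.0, 0, 0]
    cloud = PointCloud(points=np.vstack([a, b]))
    clusters = euclidean_cluster(
        cloud, ClusterParams(tolerance_r=0.005, min_cluster_size=1)
    )
    assert [len(c) for c in clusters] == [50, 50]
    assert sorted(np.concatenate(clusters).tolist()) == list(range(100))


def test_chain_at_exact_tolerance_is_one_cluster():
    # inclusive <= comparison: spacing exactly at the tolerance still links
    # (0.25 is binary-exact, so the distances equal the tolerance exactly)
    pts = np.stack([np.arange(10) * 0.25, np.zeros(10), np.zeros(10)], axis=1)
    clusters = euclidean_cluster(
        PointCloud(points=pts), ClusterParams(tolerance_r=0.25, min_cluster_size=1)
    )
    assert len(clusters) == 1 and len(clusters[0]) == 10


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_clustering_matches_union_find_oracle(seed):
    g = np.random.default_rng(seed)
    pts = g.uniform(size=(200, 3))
    params = ClusterParams(tolerance_r=0.1, min_cluster_size=1)
    got = euclidean_cluster(PointCloud(points=pts), params)
    want = clusters_brute(pts, 0.1, 1)
    assert len(got) == len(want)
    for a, b in zip(got, want):
        np.testing.assert_array_equal(a, b)


def test_size_limits_discard_clusters():
    pts = np.vstack(
        [np.zeros((5, 3)), np.ones((3, 3)), np.full((2, 3), 2.0)]
    ) + np.arange(10)[:, None] * 1e-5
    clusters = euclidean_cluster(
        PointCloud(points=pts),
        ClusterParams(tolerance_r=0.01, min_cluster_size=3, max_cluster_size=4),
    )
    assert [len(c) for c in clusters] == [3]


def test_empty_cloud_rejected():
    with pytest.raises(EmptyCloudError):
        euclidean_cluster(PointCloud(points=np.empty((0, 3))), ClusterParams())


def test_select_roi_largest_and_single():
    g = np.random.default_rng(1)
    cloud = PointCloud(points=g.normal(size=(952, 3)))
    clusters = [np.arange(900), np.arange(900, 940), np.arange(940, 952)]
    roi = select_roi(clusters, cloud, strategy="largest")
    assert len(roi) == 900
    only = select_roi([np.arange(900, 940)], cloud, strategy="nearest_centroid")
    assert len(only) == 40
    with pytest.raises(ValueError):
        select_roi([], cloud)


def test_select_roi_nearest_centroid():
    # three clusters; the small middle one sits nearest the global centroid
    g = np.random.default_rng(2)
    a = g.normal(size=(60, 3)) * 0.01 + [0.0, 0, 0]
    b = g.normal(size=(30, 3)) * 0.01 + [10.0, 0, 0]
    c = g.normal(size=(10, 3)) * 0.01 + [3.4, 0, 0]
    cloud = PointCloud(points=np.vstack([a, b, c]))
    clusters = [np.arange(60), np.arange(60, 90), np.arange(90, 100)]
    roi = select_roi(clusters, cloud, strategy="nearest_centroid")
    assert len(roi) == 10


# ---------------------------------------------------------------------------
# voxel_downsample

def test_single_voxel_collapses_to_centroid():
    # 8 corners of a 0.4 mm cube all fall into one 1 mm voxel
    corners = np.array(
        [[x, y, z] for x in (0, 4e-4) for y in (0, 4e-4) for z in (0, 4e-4)]
    )
    out = voxel_downsample(PointCloud(points=corners), VoxelParams(voxel_size=1e-3))
    assert len(out) == 1
    np.testing.assert_allclose(out.points[0], [2e-4, 2e-4, 2e-4], atol=1e-12)


def test_well_separated_points_identity_up_to_order():
    g = np.random.default_rng(4)
    pts = g.uniform(0, 1, (50, 3)) * 10  # far beyond the voxel diagonal
    out = voxel_downsample(PointCloud(points=pts), VoxelParams(voxel_size=1e-3))
    assert len(out) == 50
    got = set(map(tuple, np.round(out.points, 9)))
    want = set(map(tuple, np.round(pts, 9)))
    assert got == want


def test_gaussian_blob_distribution_preserved():
    g = np.random.default_rng(5)
    pts = g.normal(scale=5e-3, size=(10000, 3)) + 0.374
    cloud = PointCloud(points=pts)
    out = voxel_downsample(cloud, VoxelParams(voxel_size=1e-3))
    assert len(out) <= len(cloud)
    for ax in range(3):
        mean_in, mean_out = pts[:, ax].mean(), out.points[:, ax].mean()
        std_in, std_out = pts[:, ax].std(), out.points[:, ax].std()
        assert abs(mean_out - mean_in) / abs(mean_in) < 0.02
        assert abs(std_out - std_in) / std_in < 0.20


def test_voxel_never_increases_count_and_keeps_centroid():
    g = np.random.default_rng(6)
    pts = g.uniform(size=(3000, 3)) * 0.05
    out = voxel_downsample(PointCloud(points=pts), VoxelParams(voxel_size=2e-3))
    assert len(out) <= 3000
    drift = np.linalg.norm(out.points.mean(axis=0) - pts.mean(axis=0))
    assert drift < 2e-3


def test_voxel_determinism_and_color_average():
    pts = np.array([[0, 0, 0], [1e-4, 0, 0], [5e-3, 0, 0]])
    cols = np.array([[0, 0, 0], [100, 100, 100], [255, 0, 0]], dtype=np.uint8)
    cloud = PointCloud(points=pts, colors=cols)
    a = voxel_downsample(cloud, VoxelParams())
    b = voxel_downsample(cloud, VoxelParams())
    np.testing.assert_array_equal(a.points, b.points)
    np.testing.assert_array_equal(a.colors[0], [50, 50, 50])


# ---------------------------------------------------------------------------
# axis_distribution_stats

def test_axis_stats_constant_and_two_point():
    three = PointCloud(points=[[0, 0, 1], [1, 0, 1], [2, 0, 1]])
    s = axis_distribution_stats(three, "z")
    assert s == AxisStats(axis="z", mean=1.0, std=0.0, n=3)
    # population convention: std of {0, 2} is 1, not sqrt(2)
    two = PointCloud(points=[[0, 0, 0], [0, 0, 2]])
    assert axis_distribution_stats(two, "z").std == pytest.approx(1.0)


def test_axis_stats_monte_carlo_consistency():
    g = np.random.default_rng(8)
    z = g.normal(0.374, 0.015, 10000)
    cloud = PointCloud(points=np.stack([np.zeros(10000), np.zeros(10000), z], axis=1))
    s = axis_distribution_stats(cloud, "z")
    assert abs(s.mean - 0.374) < 1e-3
    assert abs(s.std - 0.015) < 1e-3


def test_axis_stats_errors():
    with pytest.raises(ValueError):
        axis_distribution_stats(PointCloud(points=[[0, 0, 0]]), "z")
    with pytest.raises(ValueError):
        axis_distribution_stats(PointCloud(points=np.zeros((3, 3))), "w")
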