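"""Denoising, clustering-based ROI extraction, and voxel downsampling.

The stages mirror the standard single-view produce-scanning pipeline:

1. ``statistical_filter`` — remove sparse outliers by thresholding each
   point's mean distance to its k nearest neighbours against a band
   ``[mu - m*sigma, mu + m*sigma]`` formed from the cloud-level mean and
   standard deviation of those per-point means.
2. ``euclidean_cluster`` — partition the cloud into connected components of
   the graph linking points within a distance tolerance, then
   ``select_roi`` keeps the component holding the target object.
3. ``voxel_downsample`` — replace all points in each occupied cube of a
   regular grid by their centroid.

All standard deviations in this module are population (divide by n)
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloudio import EmptyCloudError, PointCloud

__all__ = [
    "StatFilterParams",
    "ClusterParams",
    "VoxelParams",
    "AxisStats",
    "statistical_filter",
    "euclidean_cluster",
    "select_roi",
    "voxel_downsample",
    "axis_distribution_stats",
]


@dataclass(frozen=True)
class StatFilterParams:
    """Parameters of the statistical outlier filter.

    ``neighbor_count`` is the number of nearest neighbours averaged per point;
    ``sigma_mult`` scales the acceptance band half-width (band = mu +/- m*sigma).
    """

    neighbor_count: int = 50
    sigma_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")
        if self.sigma_mult <= 0:
            raise ValueError("sigma_mult must be > 0")


@dataclass(frozen=True)
class ClusterParams:
    """Euclidean clustering parameters; ``tolerance_r`` in metres."""

    tolerance_r: float = 0.005
    min_cluster_size: int = 100
    max_cluster_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tolerance_r <= 0:
            raise ValueError("tolerance_r must be > 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.max_cluster_size is not None and self.max_cluster_size < self.min_cluster_size:
            raise ValueError("max_cluster_size must be >= min_cluster_size")


@dataclass(frozen=True)
class VoxelParams:
    """Voxel-grid downsampling edge length in metres (default 1 mm)."""

    voxel_size: float = 0.001

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


@dataclass(frozen=True)
class AxisStats:
    axis: str
    mean: float
    std: float
    n: int


def statistical_filter(
    cloud: PointCloud, params: StatFilterParams = StatFilterParams()
) -> Tuple[PointCloud, np.ndarray]:
    """Remove points whose mean k-NN distance falls outside the sigma band.

    For every point the mean Euclidean distance to its ``neighbor_count``
    nearest neighbours (self excluded) is computed; ``mu`` and ``sigma`` are
    the mean and population standard deviation of these per-point means over
    the whole cloud.  Points outside the closed band
    ``[mu - sigma_mult*sigma, mu + sigma_mult*sigma]`` are removed.

    Returns the filtered cloud and the sorted array of removed indices
    (against input order).  When all per-point means coincide (sigma == 0)
    nothing is removed.
    """
    n = len(cloud)
    if n <= params.neighbor_count:
        raise ValueError(
            f"cloud has {n} points; need more than neighbor_count={params.neighbor_count}"
        )
    mean_dist = mean_knn_distance(cloud.points, params.neighbor_count)
    mu = float(mean_dist.mean())
    sigma = float(mean_dist.std())  # population
    if sigma == 0.0:
        removed = np.empty(0, dtype=np.intp)
    else:
        lo, hi = mu - params.sigma_mult * sigma, mu + params.sigma_mult * sigma
        removed = np.flatnonzero((mean_dist < lo) | (mean_dist > hi))
    keep = np.setdiff1d(np.arange(n), removed, assume_unique=True)
    return cloud.select(keep), removed


def mean_knn_distance(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest neighbours (self excluded)."""
    tree = cKDTree(points)
    # column 0 is the point itself (distance 0)
    dists, _ = tree.query(points, k=k + 1, workers=-1)
    return dists[:, 1:].mean(axis=1)


def euclidean_cluster(
    cloud: PointCloud, params: ClusterParams = ClusterParams()
) -> List[np.ndarray]:
    """Connected components of the <= tolerance_r proximity graph.

    Components outside [min_cluster_size, max_cluster_size] are discarded.
    Clusters are returned as sorted index arrays, ordered by size descending
    (ties broken by the smallest contained index, so output is deterministic).
    """
    n = len(cloud)
    if n == 0:
        raise EmptyCloudError("cannot cluster an empty cloud")
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(params.tolerance_r, output_type="ndarray")
    if len(pairs):
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    clusters = []
    order = np.argsort(labels, kind="stable")
    boundaries = np.flatnonzero(np.diff(labels[order])) + 1
    for idx in np.split(order, boundaries):
        size = len(idx)
        if size < params.min_cluster_size:
            continue
        if params.max_cluster_size is not None and size > params.max_cluster_size:
            continue
        clusters.append(np.sort(idx))
    clusters.sort(key=lambda c: (-len(c), int(c[0])))
    return clusters


def select_roi(
    clusters: List[np.ndarray], cloud: PointCloud, strategy: str = "largest"
) -> PointCloud:
    """Pick the target cluster and return its sub-cloud.

    ``largest`` keeps the most populous cluster; ``nearest_centroid`` keeps
    the cluster whose centroid is closest to the full-cloud centroid.
    """
    if not clusters:
        raise ValueError("no clusters to select from")
    if strategy == "largest":
        chosen = clusters[0]  # euclidean_cluster sorts by size descending
    elif strategy == "nearest_centroid":
        full_centroid = cloud.points.mean(axis=0)
        dists = [
            np.linalg.norm(cloud.points[c].mean(axis=0) - full_centroid) for c in clusters
        ]
        chosen = clusters[int(np.argmin(dists))]
    else:
        raise ValueError(f"unknown ROI strategy {strategy!r}")
    return cloud.select(chosen, source=f"{cloud.source}|roi:{strategy}")


def voxel_indices(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Integer (i,j,k) voxel coordinates, grid anchored at the min corner.

    Floor convention: a point exactly on a voxel boundary belongs to the
    lower-index voxel.
    """
    origin = points.min(axis=0)
    return np.floor((points - origin) / voxel_size).astype(np.int64)


def voxel_downsample(
    cloud: PointCloud, params: VoxelParams = VoxelParams()
) -> PointCloud:
    """Replace the points of each occupied voxel by their centroid.

    The grid is anchored at the cloud's minimum corner, so the result is
    translation-consistent within a run.  Output points are sorted by voxel
    index (lexicographic i, j, k) for determinism.  Colors, when present,
    are averaged per voxel.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot downsample an empty cloud")
    vidx = voxel_indices(cloud.points, params.voxel_size)
    # unique rows come back lexicographically sorted
    uniq, inverse = np.unique(vidx, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    n_vox = len(uniq)
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)
    centroids = np.empty((n_vox, 3))
    for d in range(3):
        centroids[:, d] = np.bincount(inverse, weights=cloud.points[:, d], minlength=n_vox)
    centroids /= counts[:, None]
    colors = None
    if cloud.colors is not None:
        colors = np.empty((n_vox, 3))
        for d in range(3):
            colors[:, d] = np.bincount(
                inverse, weights=cloud.colors[:, d].astype(np.float64), minlength=n_vox
            )
        colors = np.clip(np.round(colors / counts[:, None]), 0, 255).astype(np.uint8)
    return PointCloud(points=centroids, colors=colors, source=f"{cloud.source}|voxel")


def axis_distribution_stats(cloud: PointCloud, axis: str) -> AxisStats:
    """Mean and population standard deviation of one coordinate axis."""
    try:
        ax = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ValueError(f"axis must be x, y or z, got {axis!r}") from None
    n = len(cloud)
    if n < 2:
        raise ValueError("need at least 2 points for distribution statistics")
    coord = cloud.points[:, ax]
    return AxisStats(axis=axis, mean=float(coord.mean()), std=float(coord.std()), n=n)
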