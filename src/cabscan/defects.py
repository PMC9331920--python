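"""Two-stage curvature-threshold defect extraction and dent/crack typing.

Stage one keeps points whose surface-variation curvature ``kappa`` exceeds a
fixed threshold (default 0.08, the empirical split between intact produce
surface and damaged-edge curvature); scan-boundary points are barred from
candidacy, since the open rim of a single-view patch always carries a
spurious curvature gradient.  Candidates are grouped by Euclidean
connectivity into regions.  Stage two (optional) validates each region
against the shape-parameter level S* set by the detected *feature points*
(local S-maxima): a true depression is largely concave and reaches S*, while
residual rim or stalk artifacts are convex/saddle-dominated and are
eliminated.

Each surviving region is typed as ``dent`` (round/oval) or ``crack``
(narrow, deep) from its elongation and mean depth below the local reference
surface, with an area estimate of one voxel footprint per point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .cloudio import PointCloud
from .preprocess import ClusterParams, euclidean_cluster
from . import surfgeom

logger = logging.getLogger(__name__)

__all__ = [
    "DefectParams",
    "DefectRegion",
    "threshold_candidates",
    "refine_by_feature_threshold",
    "form_regions",
    "classify_region",
    "region_area",
    "otsu_kappa_threshold",
    "detect",
]


@dataclass(frozen=True)
class DefectParams:
    """Tunable knobs of the defect extractor.

    ``kappa_threshold`` — stage-one curvature cut (dimensionless, in (0, 1/3)).
    ``use_feature_threshold`` — enable the stage-two shape-parameter cut.
    ``exclude_boundary`` — bar open-rim points from candidacy.
    ``region_tolerance`` — Euclidean grouping distance for candidate points, metres.
    ``min_region_points`` — discard smaller groups.
    ``region_validation_frac`` — stage two keeps a region when at least this
    fraction of its points passes the shape-parameter cut (a true depression
    is largely concave; rim/stalk artifacts are convex or saddle-like and
    fall below it).
    ``elongation_cutoff`` / ``depth_cutoff_mm`` — dent/crack decision: a region
    is a crack when elongation >= cutoff or mean depth >= cutoff.
    ``auto_threshold`` — replace ``kappa_threshold`` by an Otsu split of the
    kappa histogram.
    """

    kappa_threshold: float = 0.08
    use_feature_threshold: bool = False
    exclude_boundary: bool = True
    region_tolerance: float = 0.008
    min_region_points: int = 10
    region_validation_frac: float = 0.25
    elongation_cutoff: float = 3.6
    depth_cutoff_mm: float = 5.0
    auto_threshold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa_threshold < 1.0 / 3.0:
            raise ValueError("kappa_threshold must lie in (0, 1/3)")
        if self.region_tolerance <= 0:
            raise ValueError("region_tolerance must be > 0")
        if self.min_region_points < 1:
            raise ValueError("min_region_points must be >= 1")


@dataclass
class DefectRegion:
    """A connected candidate group with its morphology descriptors."""

    point_indices: np.ndarray
    defect_type: str = "unknown"          # dent | crack | unknown
    area_mm2: float = 0.0
    kappa_max: float = 0.0
    elongation: float = 1.0
    mean_depth_mm: float = 0.0


def otsu_kappa_threshold(kappa: np.ndarray, bins: int = 256) -> float:
    """Otsu split of the kappa histogram (automatic threshold alternative)."""
    kappa = np.asarray(kappa, dtype=float)
    kappa = kappa[np.isfinite(kappa)]
    hist, edges = np.histogram(kappa, bins=bins, range=(0.0, 1.0 / 3.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    if total == 0:
        return 0.08
    w0 = np.cumsum(hist)
    w1 = total - w0
    m = np.cumsum(hist * centers)
    m_tot = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m_tot - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    # upper edge of the argmax bin, so the low class is entirely <= threshold
    # under the `kappa > threshold` candidacy convention
    return float(edges[int(np.argmax(between)) + 1])


def threshold_candidates(
    field: pd.DataFrame, params: DefectParams = DefectParams()
) -> np.ndarray:
    """Stage one: indices with kappa above the curvature threshold.

    Scan-boundary points are excluded when ``params.exclude_boundary``.
    """
    kappa = field["kappa"].to_numpy(dtype=float)
    thr = (
        otsu_kappa_threshold(kappa) if params.auto_threshold else params.kappa_threshold
    )
    mask = kappa > thr
    if params.exclude_boundary and "boundary" in field:
        mask &= ~field["boundary"].to_numpy(dtype=bool)
    return np.flatnonzero(mask)


def refine_by_feature_threshold(
    candidates: np.ndarray, field: pd.DataFrame, feature_pts: np.ndarray
) -> np.ndarray:
    """Stage two: keep candidates whose S reaches the feature-point level.

    The second threshold ``S*`` is the minimum shape parameter over the
    detected feature points; candidates with ``S >= S*`` survive.  With no
    feature points the candidate set is returned unchanged (warning logged).
    """
    candidates = np.asarray(candidates, dtype=np.intp)
    if len(feature_pts) == 0:
        logger.warning("no feature points found; skipping stage-two refinement")
        return candidates
    s = field["S"].to_numpy(dtype=float)
    s_star = np.nanmin(s[np.asarray(feature_pts, dtype=np.intp)])
    keep = np.isfinite(s[candidates]) & (s[candidates] >= s_star)
    return candidates[keep]


def _elongation_3d(points: np.ndarray) -> float:
    """Ratio of the two largest covariance-eigenvalue square roots (>= 1)."""
    if len(points) < 3:
        return 1.0
    d = points - points.mean(axis=0)
    cov = d.T @ d / len(points)
    evals = np.linalg.eigvalsh(cov)          # ascending
    major, minor = evals[2], evals[1]
    if minor <= 0:
        return np.inf if major > 0 else 1.0
    return float(np.sqrt(major / minor))


def _region_geometry(
    region_idx: np.ndarray,
    candidate_set: np.ndarray,
    cloud: PointCloud,
    margin: float = 2.0,
) -> Tuple[float, float]:
    """Surface-plane elongation and mean depth (mm) of one region.

    A reference surface (full quadratic height field) is fitted to the
    *non-candidate* points within ``margin`` times the region radius, in the
    PCA frame of that surrounding ring.  Depth is the magnitude of the mean
    signed residual of region points against it: a depression sits coherently
    on one side, while rim-like false positives straddle it and average out.
    Elongation is the axis ratio of the region's footprint *in the tangent
    plane* of that frame — narrowness is a surface property, and using the
    3D covariance would let the depth of a deep crack mask its narrow shape.
    """
    pts = cloud.points
    region_pts = pts[region_idx]
    center = region_pts.mean(axis=0)
    radius = np.linalg.norm(region_pts - center, axis=1).max()
    radius = max(radius, 1e-3)
    cand_mask = np.zeros(len(pts), dtype=bool)
    cand_mask[candidate_set] = True
    near = np.linalg.norm(pts - center, axis=1) <= margin * radius
    ring = near & ~cand_mask
    if ring.sum() < 12:
        return _elongation_3d(region_pts), 0.0
    ring_pts = pts[ring]
    d = ring_pts - ring_pts.mean(axis=0)
    cov = d.T @ d / len(ring_pts)
    _, evecs = np.linalg.eigh(cov)
    frame = np.stack([evecs[:, 2], evecs[:, 1], evecs[:, 0]], axis=0)
    origin = ring_pts.mean(axis=0)

    def to_local(p):
        return (p - origin) @ frame.T

    ring_local = to_local(ring_pts)
    x, y, z = ring_local[:, 0], ring_local[:, 1], ring_local[:, 2]
    design = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=1)
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    reg_local = to_local(region_pts)
    xr, yr, zr = reg_local[:, 0], reg_local[:, 1], reg_local[:, 2]
    design_r = np.stack([np.ones_like(xr), xr, yr, xr * xr, xr * yr, yr * yr], axis=1)
    z_ref = design_r @ coef
    depth_mm = abs(float((zr - z_ref).mean())) * 1000.0

    uv = np.stack([xr - xr.mean(), yr - yr.mean()], axis=1)
    cov2 = uv.T @ uv / len(uv)
    e2 = np.linalg.eigvalsh(cov2)
    if e2[0] <= 0:
        elong = np.inf if e2[1] > 0 else 1.0
    else:
        elong = float(np.sqrt(e2[1] / e2[0]))
    return elong, depth_mm


def form_regions(
    candidate_set: np.ndarray,
    cloud: PointCloud,
    params: DefectParams = DefectParams(),
    field: Optional[pd.DataFrame] = None,
) -> List[DefectRegion]:
    """Group candidates into connected regions and attach morphology.

    Reuses Euclidean clustering at ``region_tolerance``; groups smaller than
    ``min_region_points`` are dropped.  Each region carries kappa_max,
    elongation and mean depth (mm) below the locally fitted reference
    surface.
    """
    candidate_set = np.asarray(candidate_set, dtype=np.intp)
    if len(candidate_set) == 0:
        return []
    sub = cloud.select(candidate_set, source=f"{cloud.source}|candidates")
    clusters = euclidean_cluster(
        sub,
        ClusterParams(
            tolerance_r=params.region_tolerance,
            min_cluster_size=params.min_region_points,
        ),
    )
    regions: List[DefectRegion] = []
    kappa = field["kappa"].to_numpy(dtype=float) if field is not None else None
    for local_idx in clusters:
        idx = candidate_set[local_idx]
        region = DefectRegion(point_indices=idx)
        region.elongation, region.mean_depth_mm = _region_geometry(
            idx, candidate_set, cloud
        )
        if kappa is not None:
            region.kappa_max = float(np.nanmax(kappa[idx]))
        regions.append(region)
    return regions


def classify_region(
    region: DefectRegion, params: DefectParams = DefectParams()
) -> str:
    """Type a region: crack when narrow or deep, dent otherwise."""
    if region.point_indices is None or len(region.point_indices) == 0:
        raise ValueError("region has no points")
    if (
        region.elongation >= params.elongation_cutoff
        or region.mean_depth_mm >= params.depth_cutoff_mm
    ):
        return "crack"
    return "dent"


def region_area(region: DefectRegion, voxel_size: float) -> float:
    """Area estimate in mm^2: one voxel footprint per surviving point."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    return len(region.point_indices) * (voxel_size * 1000.0) ** 2


def detect(
    cloud: PointCloud,
    params: DefectParams = DefectParams(),
    k: int = 50,
    voxel_size: float = 0.001,
    viewpoint=surfgeom.DEFAULT_VIEWPOINT,
    field: Optional[pd.DataFrame] = None,
) -> tuple[List[DefectRegion], np.ndarray]:
    """End-to-end defect extraction on a preprocessed (ROI, voxelised) cloud.

    Stage one thresholds the curvature field and groups candidates into
    connected regions; stage two keeps only regions in which a sufficient
    fraction of points reaches the feature-point shape level S* — a
    depression is largely concave and passes, while residual rim or stalk
    artifacts are convex/saddle-dominated and are eliminated.  Returns the
    typed regions and a per-point label array (1 = intact surface,
    2 = dent, 3 = crack).  An intact cloud yields an empty region list.  A
    precomputed curvature ``field`` may be supplied to avoid recomputation.
    """
    if field is None:
        field = surfgeom.curvature_field(cloud, k=k, viewpoint=viewpoint)
    candidates = threshold_candidates(field, params)
    regions = form_regions(candidates, cloud, params, field=field)
    if params.use_feature_threshold and regions:
        feats = surfgeom.feature_points(field, cloud, k=k)
        refined = set(refine_by_feature_threshold(candidates, field, feats).tolist())
        regions = [
            r
            for r in regions
            if sum(int(i) in refined for i in r.point_indices)
            >= params.region_validation_frac * len(r.point_indices)
        ]
    labels = np.ones(len(cloud), dtype=np.int8)
    for region in regions:
        region.defect_type = classify_region(region, params)
        region.area_mm2 = region_area(region, voxel_size)
        labels[region.point_indices] = 2 if region.defect_type == "dent" else 3
    return regions, labels
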