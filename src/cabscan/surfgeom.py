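"""Per-point differential geometry of an unorganized point cloud.

For every point we analyse its k-nearest-neighbour patch twice:

* **Covariance analysis** — the 3x3 covariance of the neighbours yields
  eigenvalues ``lambda0 <= lambda1 <= lambda2``; the eigenvector of the
  smallest eigenvalue is the surface normal and the *surface variation*

      kappa = lambda0 / (lambda0 + lambda1 + lambda2)

  is a bounded curvature proxy in [0, 1/3]: 0 on exact planes, 1/3 for a
  fully isotropic neighbourhood.

* **Quadric fit** — the patch is expressed in a local frame (origin at the
  query point, +z along the viewing direction) and fitted by least squares
  with ``z = a x^2 + b x y + c y^2``.  The principal curvatures (k1 >= k2)
  are the eigenvalues of the second-fundamental-form matrix
  ``[[2a, b], [b, 2c]]`` at the origin, and feed the scale-free shape
  parameter

      S = 1/2 - (1/pi) * arctan((k1 + k2) / (k1 - k2))  in  [0, 1],

  0 at convex umbilics (bulges toward the sensor), 1 at concave umbilics
  (depressions), 0.5 on planes and symmetric saddles.

Sign convention: the local +z axis points *away* from the sensor, so a
surface bulging toward the sensor has positive principal curvatures.  The
reported per-point ``normal`` is always oriented toward the viewpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloudio import PointCloud

__all__ = [
    "NeighborhoodGeometry",
    "QuadricSurface",
    "DegenerateFitError",
    "DEFAULT_VIEWPOINT",
    "knn_neighborhood",
    "covariance_geometry",
    "fit_quadric",
    "shape_parameter",
    "curvature_field",
    "feature_points",
    "field_to_csv",
    "write_field_ply",
]

#: Default sensor position: on the +z axis, 10 m above the origin — far
#: enough that orientation is effectively "toward +z" for desk-scale scenes.
DEFAULT_VIEWPOINT = np.array([0.0, 0.0, 10.0])

_EPS_UMBILIC = 1e-12


class DegenerateFitError(ValueError):
    """Raised when the quadric normal equations are rank-deficient."""


@dataclass
class NeighborhoodGeometry:
    point_index: int
    neighbor_indices: np.ndarray
    centroid: np.ndarray
    eigenvalues: np.ndarray       # ascending, >= 0
    eigenvectors: np.ndarray      # columns match eigenvalues
    normal: np.ndarray            # unit, oriented toward the viewpoint
    kappa: float


@dataclass
class QuadricSurface:
    a: float
    b: float
    c: float
    frame_origin: np.ndarray
    frame_axes: np.ndarray        # rows: local x, y, z in world coordinates
    k1: float
    k2: float
    shape_S: float


# ---------------------------------------------------------------------------
# neighbour search

def knn_neighborhood(cloud: PointCloud, point_index: int, k: int) -> np.ndarray:
    """Indices of the k nearest points to ``point_index`` (self excluded).

    Exact distance ties are broken toward the lower index, so the result is
    fully deterministic even for duplicated points.
    """
    n = len(cloud)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cloud size {n}")
    pts = cloud.points
    tree = cKDTree(pts)
    m = min(n, k + 8)
    _, cand = tree.query(pts[point_index], k=m)
    cand = np.atleast_1d(cand)
    cand = cand[cand != point_index]
    d2 = ((pts[cand] - pts[point_index]) ** 2).sum(axis=1)
    order = np.lexsort((cand, d2))
    cand, d2 = cand[order], d2[order]
    # a tie straddling the cut, or an exhausted candidate pool, needs the
    # full distance ranking to honour the lower-index rule
    if len(cand) < k or (len(cand) > k and d2[k - 1] == d2[k]) or m < n:
        if len(cand) > k and d2[k - 1] != d2[k]:
            return cand[:k]
        d2_all = ((pts - pts[point_index]) ** 2).sum(axis=1)
        idx_all = np.arange(n)
        mask = idx_all != point_index
        idx_all, d2_all = idx_all[mask], d2_all[mask]
        order = np.lexsort((idx_all, d2_all))
        return idx_all[order][:k]
    return cand[:k]


def _knn_batch(points: np.ndarray, k: int) -> np.ndarray:
    """(n, k) neighbour-index array for every point, self excluded."""
    n = len(points)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cloud size {n}")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1, workers=-1)
    # the self column is normally column 0; with duplicated points it can
    # appear later (or not at all within k+1)
    rows = np.arange(n)[:, None]
    is_self = idx == rows
    out = np.empty((n, k), dtype=np.intp)
    normal_rows = is_self[:, 0]
    out[normal_rows] = idx[normal_rows, 1:]
    odd = np.flatnonzero(~normal_rows)
    for i in odd:
        row = idx[i]
        row = row[row != i]
        out[i] = row[:k]
    return out


# ---------------------------------------------------------------------------
# covariance geometry

def _covariance_batch(
    points: np.ndarray,
    nbr: np.ndarray,
    viewpoint: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised covariance analysis over an (n, k) neighbour table.

    Returns (centroids, eigenvalues, eigenvectors, normals, kappa).
    Eigenvalues ascending with tiny negatives clamped to 0; normals unit and
    oriented toward ``viewpoint``.
    """
    nbr_pts = points[nbr]                       # (n, k, 3)
    centroid = nbr_pts.mean(axis=1)             # (n, 3)
    d = nbr_pts - centroid[:, None, :]
    cov = np.einsum("nki,nkj->nij", d, d) / nbr.shape[1]
    evals, evecs = np.linalg.eigh(cov)          # ascending
    evals = np.where((evals > -1e-12) & (evals < 0), 0.0, evals)
    normals = evecs[:, :, 0]
    to_vp = viewpoint[None, :] - points[: len(nbr)]
    flip = np.einsum("ni,ni->n", normals, to_vp) < 0
    normals = np.where(flip[:, None], -normals, normals)
    total = evals.sum(axis=1)
    kappa = np.divide(
        evals[:, 0], total, out=np.zeros(len(nbr)), where=total > 0
    )
    return centroid, evals, evecs, normals, kappa


def covariance_geometry(
    cloud: PointCloud,
    point_index: int,
    k: int = 50,
    viewpoint: Union[np.ndarray, Iterable[float]] = DEFAULT_VIEWPOINT,
) -> NeighborhoodGeometry:
    """Covariance eigen-analysis of the k-neighbour patch of one point.

    The covariance is formed over the k neighbours only (the query point is
    excluded), centred at their centroid.  Requires ``k >= 3``.
    """
    if k < 3:
        raise ValueError("k must be >= 3 for a surface covariance")
    nbr = knn_neighborhood(cloud, point_index, k)
    pts = cloud.points
    query = pts[point_index][None, :]
    centroid, evals, evecs, normals, kappa = _covariance_batch(
        np.vstack([pts, query]), nbr[None, :], np.asarray(viewpoint, dtype=float)
    )
    # _covariance_batch orients against points[:len(nbr_table)]; redo with query pt
    to_vp = np.asarray(viewpoint, dtype=float) - pts[point_index]
    normal = evecs[0][:, 0]
    if normal @ to_vp < 0:
        normal = -normal
    return NeighborhoodGeometry(
        point_index=point_index,
        neighbor_indices=nbr,
        centroid=centroid[0],
        eigenvalues=evals[0],
        eigenvectors=evecs[0],
        normal=normal,
        kappa=float(kappa[0]),
    )


# ---------------------------------------------------------------------------
# quadric fit

def _local_frames(
    normals: np.ndarray, evecs: np.ndarray, points: np.ndarray, viewpoint: np.ndarray
) -> np.ndarray:
    """Right-handed local frames, rows (x, y, z), z along the viewing direction.

    x is the tangent eigenvector of the largest covariance eigenvalue with a
    deterministic sign (largest-|component| coordinate made positive).
    """
    n = len(normals)
    z = -(normals)  # normals point toward the sensor; +z looks away from it
    x = evecs[:, :, 2]  # largest-eigenvalue direction, tangent to the patch
    # remove any z component (numerically tiny; eigenvectors are orthogonal)
    x = x - np.einsum("ni,ni->n", x, z)[:, None] * z
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    dom = np.argmax(np.abs(x), axis=1)
    sign = np.sign(x[np.arange(n), dom])
    x *= sign[:, None]
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def _quadric_batch(
    points: np.ndarray,
    nbr: np.ndarray,
    frames: np.ndarray,
    origins: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares ``z = a x^2 + b x y + c y^2`` per point, in local frames.

    Returns (coeffs (n,3), k1, k2, ok-mask).  Points with rank-deficient
    normal equations get ok=False and NaN coefficients/curvatures.
    """
    local = np.einsum(
        "nij,nkj->nki", frames, points[nbr] - origins[:, None, :]
    )  # (n, k, 3)
    x, y, z = local[..., 0], local[..., 1], local[..., 2]
    design = np.stack([x * x, x * y, y * y], axis=-1)          # (n, k, 3)
    ata = np.einsum("nki,nkj->nij", design, design)
    atz = np.einsum("nki,nk->ni", design, z)
    scale = np.trace(ata, axis1=1, axis2=2) / 3.0
    ok = np.zeros(len(nbr), dtype=bool)
    coeffs = np.full((len(nbr), 3), np.nan)
    solvable = scale > 0
    if solvable.any():
        ata_s = ata[solvable]
        det = np.linalg.det(ata_s)
        good = np.abs(det) > (scale[solvable] ** 3) * 1e-12
        idx = np.flatnonzero(solvable)[good]
        if len(idx):
            coeffs[idx] = np.linalg.solve(ata[idx], atz[idx][..., None])[..., 0]
            ok[idx] = True
    a, b, c = coeffs[:, 0], coeffs[:, 1], coeffs[:, 2]
    # eigenvalues of [[2a, b], [b, 2c]]
    tr = a + c
    disc = np.sqrt((a - c) ** 2 + b * b)
    k1 = tr + disc
    k2 = tr - disc
    return coeffs, k1, k2, ok


def fit_quadric(
    cloud: PointCloud,
    point_index: int,
    k: int = 60,
    viewpoint: Union[np.ndarray, Iterable[float]] = DEFAULT_VIEWPOINT,
) -> QuadricSurface:
    """Fit the local quadric at one point and derive principal curvatures.

    The local frame sits at the query point with +z along the viewing
    direction (covariance normal flipped away from the sensor); the fit model
    has no constant or linear term, which is valid at the surface point
    itself.  Raises :class:`DegenerateFitError` for rank-deficient patches
    (e.g. all neighbours collinear in the local frame).
    """
    if k < 6:
        raise ValueError("k must be >= 6 for a quadric fit")
    vp = np.asarray(viewpoint, dtype=float)
    geom = covariance_geometry(cloud, point_index, k=k, viewpoint=vp)
    if geom.eigenvalues[1] <= 0:
        raise DegenerateFitError("neighborhood is degenerate (lambda1 == 0)")
    pts = cloud.points
    frames = _local_frames(
        geom.normal[None, :], geom.eigenvectors[None, :, :], pts[[point_index]], vp
    )
    coeffs, k1, k2, ok = _quadric_batch(
        pts, geom.neighbor_indices[None, :], frames, pts[[point_index]]
    )
    if not ok[0]:
        raise DegenerateFitError("rank-deficient quadric normal equations")
    a, b, c = coeffs[0]
    return QuadricSurface(
        a=float(a),
        b=float(b),
        c=float(c),
        frame_origin=pts[point_index].copy(),
        frame_axes=frames[0],
        k1=float(k1[0]),
        k2=float(k2[0]),
        shape_S=shape_parameter(float(k1[0]), float(k2[0])),
    )


def shape_parameter(k1: float, k2: float) -> float:
    """Scale-free shape parameter S in [0, 1] from principal curvatures.

    ``S = 1/2 - (1/pi) arctan((k1 + k2)/(k1 - k2))`` for k1 > k2.  At
    umbilics (|k1 - k2| <= eps) the arctan limit applies: 0 for convex
    (k1 + k2 > 0), 1 for concave, 0.5 for flat.
    """
    hi, lo = (k1, k2) if k1 >= k2 else (k2, k1)
    diff = hi - lo
    tot = hi + lo
    if diff <= _EPS_UMBILIC:
        if tot > _EPS_UMBILIC:
            return 0.0
        if tot < -_EPS_UMBILIC:
            return 1.0
        return 0.5
    return 0.5 - np.arctan2(tot, diff) / np.pi


def _shape_parameter_vec(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    diff = k1 - k2
    tot = k1 + k2
    with np.errstate(invalid="ignore"):
        s = 0.5 - np.arctan2(tot, diff) / np.pi
    umb = np.abs(diff) <= _EPS_UMBILIC
    s = np.where(umb & (tot > _EPS_UMBILIC), 0.0, s)
    s = np.where(umb & (tot < -_EPS_UMBILIC), 1.0, s)
    s = np.where(umb & (np.abs(tot) <= _EPS_UMBILIC), 0.5, s)
    return s


def _boundary_flags(
    pts: np.ndarray,
    nbr: np.ndarray,
    frames: np.ndarray,
    max_gap: float = 2.0,
) -> np.ndarray:
    """Open-rim detection by the tangent-plane angular-gap criterion.

    Neighbours are projected into each point's tangent plane; a point whose
    neighbours leave an angular sector wider than ``max_gap`` radians empty
    is an open-boundary (scan rim) point.  Interior points — including those
    on steep defect walls — are surrounded in the tangent plane and show
    only small gaps.
    """
    rel = pts[nbr] - pts[:, None, :]                    # (n, k, 3)
    u = np.einsum("nkj,nj->nk", rel, frames[:, 0, :])
    v = np.einsum("nkj,nj->nk", rel, frames[:, 1, :])
    ang = np.sort(np.arctan2(v, u), axis=1)
    gaps = np.diff(ang, axis=1)
    wrap = 2 * np.pi - (ang[:, -1] - ang[:, 0])
    max_gaps = np.maximum(gaps.max(axis=1), wrap)
    return max_gaps > max_gap


# ---------------------------------------------------------------------------
# whole-cloud field

def curvature_field(
    cloud: PointCloud,
    k: int = 50,
    viewpoint: Union[np.ndarray, Iterable[float]] = DEFAULT_VIEWPOINT,
) -> pd.DataFrame:
    """Covariance curvature, quadric curvatures and shape parameter per point.

    Returns a DataFrame indexed by point with columns
    ``x, y, z, kappa, k1, k2, S, nx, ny, nz, boundary, s_defined``.
    ``s_defined`` is False where the quadric fit is degenerate (kappa is
    still reported there).  ``boundary`` flags points whose neighbourhood
    centroid is offset from the point by more than half the mean neighbour
    distance — the signature of an open scan rim.
    """
    n = len(cloud)
    if n <= k:
        raise ValueError(f"cloud size {n} must exceed k={k}")
    vp = np.asarray(viewpoint, dtype=float)
    pts = cloud.points
    nbr = _knn_batch(pts, k)
    centroid, evals, evecs, normals, kappa = _covariance_batch(pts, nbr, vp)

    frames = _local_frames(normals, evecs, pts, vp)
    boundary = _boundary_flags(pts, nbr, frames)
    nondeg = evals[:, 1] > 0
    coeffs = np.full((n, 3), np.nan)
    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    if nondeg.any():
        c_, k1_, k2_, ok_ = _quadric_batch(
            pts, nbr[nondeg], frames[nondeg], pts[nondeg]
        )
        coeffs[nondeg] = c_
        k1[nondeg] = k1_
        k2[nondeg] = k2_
        ok[nondeg] = ok_
    S = np.full(n, np.nan)
    S[ok] = _shape_parameter_vec(k1[ok], k2[ok])

    return pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "kappa": kappa,
            "k1": k1,
            "k2": k2,
            "S": S,
            "nx": normals[:, 0],
            "ny": normals[:, 1],
            "nz": normals[:, 2],
            "boundary": boundary,
            "s_defined": ok,
        }
    )


def feature_points(field: pd.DataFrame, cloud: PointCloud, k: int = 50) -> np.ndarray:
    """Indices whose S strictly exceeds the max S of their k nearest neighbours.

    Points without a defined S never qualify and never block a neighbour
    (their S is ignored in the neighbour maximum).
    """
    pts = cloud.points
    nbr = _knn_batch(pts, k)
    s = field["S"].to_numpy(dtype=float)
    defined = field["s_defined"].to_numpy(dtype=bool) & np.isfinite(s)
    s_masked = np.where(defined, s, -np.inf)
    nbr_max = s_masked[nbr].max(axis=1)
    qualifies = defined & (s > nbr_max)
    return np.flatnonzero(qualifies)


# ---------------------------------------------------------------------------
# export

def field_to_csv(field: pd.DataFrame, path) -> None:
    """Write the per-point field as CSV (index, coordinates, curvatures, normal)."""
    cols = ["x", "y", "z", "kappa", "k1", "k2", "S", "nx", "ny", "nz"]
    field[cols].to_csv(path, index_label="index")


def write_field_ply(field: pd.DataFrame, path) -> None:
    """ASCII PLY with kappa as a scalar vertex property for external viewers."""
    n = len(field)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment units: metres\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float kappa\nend_header\n")
        for row in field.itertuples():
            fh.write(f"{row.x:.9g} {row.y:.9g} {row.z:.9g} {row.kappa:.9g}\n")
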