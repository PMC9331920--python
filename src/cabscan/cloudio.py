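"""Point-cloud container and ASCII readers/writers for PLY, PCD and XYZ.

The :class:`PointCloud` is the currency of every pipeline stage: an ordered
array of (x, y, z) coordinates in metres, optionally with per-point RGB
colors that are carried through but never consumed by the geometry code.

Only the ASCII dialects of PLY and PCD are supported; they are the plain-text
interchange formats the rest of the toolchain (and third-party viewers) read.
Rows with non-finite coordinates are dropped on load and the count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "CloudFormatError",
    "EmptyCloudError",
    "read_cloud",
    "write_cloud",
]


class CloudFormatError(ValueError):
    """Raised for unparseable files or unknown formats."""


class EmptyCloudError(ValueError):
    """Raised when an operation requires a non-empty cloud."""


@dataclass
class PointCloud:
    """An unorganized 3D point cloud.

    Parameters
    ----------
    points
        (n, 3) float array of coordinates in metres.
    colors
        Optional (n, 3) uint8 array of RGB values, one row per point.
    source
        Free-text provenance tag (file path, generator spec, stage name).
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError(
                    f"colors ({len(self.colors)}) and points ({len(self.points)}) "
                    "must have the same length"
                )

    def __len__(self) -> int:
        return len(self.points)

    def select(self, indices: Union[np.ndarray, Sequence[int]], source: str = "") -> "PointCloud":
        """Sub-cloud at the given indices (order preserved as given)."""
        idx = np.asarray(indices)
        return PointCloud(
            points=self.points[idx],
            colors=None if self.colors is None else self.colors[idx],
            source=source or self.source,
        )


_FORMATS = ("ply", "pcd", "xyz")


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("txt", "asc"):
        ext = "xyz"
    if ext not in _FORMATS:
        raise CloudFormatError(f"cannot auto-detect cloud format from extension {path.suffix!r}")
    return ext


def read_cloud(path: Union[str, Path], format: str = "auto") -> PointCloud:
    """Read a point cloud from an ASCII PLY, PCD or XYZ file.

    Non-finite rows (NaN/Inf) are dropped; the number removed is logged.
    Raises :class:`EmptyCloudError` if no finite point remains.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in _FORMATS:
        raise CloudFormatError(f"unknown cloud format {format!r}")

    if fmt == "ply":
        pts, cols = _read_ply(path)
    elif fmt == "pcd":
        pts, cols = _read_pcd(path)
    else:
        pts, cols = _read_xyz(path)

    finite = np.isfinite(pts).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_cloud: dropped %d non-finite rows from %s", n_dropped, path)
        pts = pts[finite]
        cols = cols[finite] if cols is not None else None
    if len(pts) == 0:
        raise EmptyCloudError(f"no finite points in {path}")
    return PointCloud(points=pts, colors=cols, source=str(path))


def write_cloud(cloud: PointCloud, path: Union[str, Path], format: str = "auto") -> Path:
    """Write a cloud to ASCII PLY, PCD or XYZ. Returns the path written.

    Coordinates are written with 9 significant digits (repr-stable well below
    the 1e-6 m round-trip tolerance); writing is deterministic, so a second
    write of a re-read cloud is byte-identical.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in _FORMATS:
        raise CloudFormatError(f"unknown cloud format {format!r}")
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    else:
        _write_xyz(cloud, path)
    return path


# ---------------------------------------------------------------------------
# PLY (ASCII, element vertex with x,y,z[,red,green,blue])

def _read_ply(path: Path):
    with open(path, "r") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise CloudFormatError(f"{path}: missing 'ply' magic")
        n_vertex = None
        props: list[str] = []
        in_vertex = False
        fmt_ascii = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: truncated PLY header")
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt_ascii = tok[1] == "ascii"
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        if not fmt_ascii:
            raise CloudFormatError(f"{path}: only ASCII PLY is supported")
        if n_vertex is None:
            raise CloudFormatError(f"{path}: no vertex element")
        try:
            ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
        except ValueError as exc:
            raise CloudFormatError(f"{path}: vertex element lacks x/y/z") from exc
        data = np.loadtxt(fh, dtype=np.float64, max_rows=n_vertex, ndmin=2)
    if data.shape[0] != n_vertex:
        raise CloudFormatError(f"{path}: expected {n_vertex} vertices, got {data.shape[0]}")
    pts = data[:, [ix, iy, iz]]
    cols = None
    if {"red", "green", "blue"} <= set(props):
        ic = [props.index(c) for c in ("red", "green", "blue")]
        cols = data[:, ic].astype(np.uint8)
    return pts, cols


def _write_ply(cloud: PointCloud, path: Path) -> None:
    has_color = cloud.colors is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write("comment units: metres\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_color:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for i, (x, y, z) in enumerate(cloud.points):
            if has_color:
                r, g, b = cloud.colors[i]
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {r} {g} {b}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# PCD v0.7 ASCII (FIELDS x y z [rgb]; rgb packed as a float-encoded uint32)

def _read_pcd(path: Path):
    fields: list[str] = []
    n_points = None
    data_started = False
    rows = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not data_started:
                tok = line.split()
                key = tok[0].upper()
                if key == "FIELDS":
                    fields = tok[1:]
                elif key == "POINTS":
                    n_points = int(tok[1])
                elif key == "DATA":
                    if tok[1] != "ascii":
                        raise CloudFormatError(f"{path}: only ASCII PCD is supported")
                    data_started = True
                continue
            rows.append(line.split())
    if not data_started:
        raise CloudFormatError(f"{path}: no DATA section")
    try:
        ix, iy, iz = fields.index("x"), fields.index("y"), fields.index("z")
    except ValueError as exc:
        raise CloudFormatError(f"{path}: FIELDS lacks x/y/z") from exc
    data = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(fields)))
    if n_points is not None and data.shape[0] != n_points:
        raise CloudFormatError(f"{path}: POINTS={n_points} but {data.shape[0]} rows")
    pts = data[:, [ix, iy, iz]]
    cols = None
    if "rgb" in fields and len(data):
        packed = data[:, fields.index("rgb")].astype(np.float32).view(np.uint32)
        cols = np.stack(
            [(packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF], axis=1
        ).astype(np.uint8)
    return pts, cols


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    has_color = cloud.colors is not None
    fields = "x y z rgb" if has_color else "x y z"
    n_fields = 4 if has_color else 3
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("# units: metres\n")
        fh.write("VERSION 0.7\n")
        fh.write(f"FIELDS {fields}\n")
        fh.write(f"SIZE {' '.join(['4'] * n_fields)}\n")
        fh.write(f"TYPE {' '.join(['F'] * n_fields)}\n")
        fh.write(f"COUNT {' '.join(['1'] * n_fields)}\n")
        fh.write(f"WIDTH {len(cloud)}\nHEIGHT 1\n")
        fh.write("VIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {len(cloud)}\nDATA ascii\n")
        for i, (x, y, z) in enumerate(cloud.points):
            if has_color:
                r, g, b = (int(v) for v in cloud.colors[i])
                packed = np.uint32((r << 16) | (g << 8) | b)
                rgbf = packed.view(np.float32)
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {rgbf:.9g}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# XYZ: whitespace-separated triples, '#' comments; colors not representable

def _read_xyz(path: Path):
    rows = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 3:
                raise CloudFormatError(f"{path}: XYZ row with fewer than 3 columns")
            rows.append([float(tok[0]), float(tok[1]), float(tok[2])])
    pts = np.array(rows, dtype=np.float64) if rows else np.empty((0, 3))
    return pts, None


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z (metres)\n")
        for x, y, z in cloud.points:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
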