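"""Colored point-cloud container and I/O.

Clouds are one maize plant (or one scanned scene) after multi-station
registration: positions in meters with the z axis vertical, plus per-point
8-bit RGB from the scanner's camera. Supported on-disk formats are PLY
(ASCII and binary little-endian, properties ``x y z red green blue``),
ASCII PCD with ``FIELDS x y z rgb`` (packed-float RGB, the PCL convention)
and whitespace-delimited ``x y z r g b`` text.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "ColoredPointCloud",
    "CloudFormatError",
    "read_cloud",
    "write_cloud",
    "uniform_simplify",
    "bbox_diagonal",
]


class CloudFormatError(ValueError):
    """Raised when a point-cloud file cannot be parsed as requested."""


@dataclass
class ColoredPointCloud:
    """Point positions (n, 3) float64 meters + colors (n, 3) uint8."""

    positions: np.ndarray
    colors: np.ndarray
    labels: np.ndarray | None = field(default=None, repr=False)
    """Optional per-point integer labels (used by the synthetic generator)."""

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.colors = np.ascontiguousarray(self.colors)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.colors.shape != self.positions.shape:
            raise ValueError("colors must match positions shape")
        if len(self.positions) < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain NaN/Inf")
        c = np.asarray(self.colors, dtype=np.float64)
        if c.min() < 0 or c.max() > 255:
            raise ValueError("RGB components must lie in [0, 255]")
        self.colors = self.colors.astype(np.uint8)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.positions):
                raise ValueError("labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.positions)

    def select(self, index: np.ndarray) -> "ColoredPointCloud":
        """Sub-cloud at the given indices / boolean mask."""
        lab = self.labels[index] if self.labels is not None else None
        return ColoredPointCloud(self.positions[index], self.colors[index], lab)


def _axis_permutation(up_axis: str) -> np.ndarray:
    """Rotation-free axis remap putting ``up_axis`` of the file onto z."""
    perm = {"z": (0, 1, 2), "y": (0, 2, 1), "x": (2, 1, 0)}
    try:
        return np.asarray(perm[up_axis])
    except KeyError:  # pragma: no cover - argument validation
        raise ValueError(f"up_axis must be one of x/y/z, got {up_axis!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return "ply"
    if ext == ".pcd":
        return "pcd"
    return "xyzrgb"


def read_cloud(
    path: str,
    format: str | None = None,
    default_color: tuple[int, int, int] | None = None,
    up_axis: str = "z",
) -> ColoredPointCloud:
    """Read a colored cloud from ``path``.

    Parameters
    ----------
    format
        ``"ply"``, ``"pcd"`` or ``"xyzrgb"``; inferred from the extension
        when omitted.
    default_color
        If given, colorless files are accepted and painted uniformly with
        this RGB triple; otherwise a missing color channel is an error.
    up_axis
        Which file axis is vertical; coordinates are permuted so that the
        returned cloud is z-up (all height-based traits assume z-up).
    """
    fmt = format or _infer_format(path)
    if fmt == "ply":
        pos, col = _read_ply(path)
    elif fmt == "pcd":
        pos, col = _read_pcd(path)
    elif fmt == "xyzrgb":
        pos, col = _read_xyzrgb(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if col is None:
        if default_color is None:
            raise CloudFormatError(
                f"{path}: no color channel present and no default color given"
            )
        col = np.tile(np.asarray(default_color, dtype=np.uint8), (len(pos), 1))
    pos = pos[:, _axis_permutation(up_axis)]
    return ColoredPointCloud(pos, col)


def write_cloud(cloud: ColoredPointCloud, path: str, format: str | None = None,
                binary: bool = False) -> None:
    """Write a cloud to disk (PLY via trimesh, PCD/XYZRGB as text)."""
    fmt = format or _infer_format(path)
    if fmt == "ply":
        pc = trimesh.PointCloud(cloud.positions, colors=cloud.colors)
        encoding = "binary_little_endian" if binary else "ascii"
        data = pc.export(file_type="ply", encoding=encoding)
        with open(path, "wb") as fh:
            fh.write(data)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    elif fmt == "xyzrgb":
        arr = np.hstack([cloud.positions, cloud.colors.astype(np.float64)])
        np.savetxt(path, arr, fmt="%.8g %.8g %.8g %d %d %d")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_ply(path: str) -> tuple[np.ndarray, np.ndarray | None]:
    try:
        obj = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:
        raise CloudFormatError(f"{path}: PLY parse failed ({exc})") from exc
    pos = np.asarray(obj.vertices, dtype=np.float64)
    if pos.size == 0:
        raise CloudFormatError(f"{path}: PLY contains no vertices")
    col = None
    try:
        colors = np.asarray(obj.colors)
    except Exception:
        colors = np.empty(0)
    if colors.size:
        col = colors[:, :3].astype(np.uint8)
    else:
        # trimesh hides per-vertex colors that it considers defaults; fall
        # back to the raw header to distinguish "absent" from "all gray".
        col = _ply_colors_fallback(path, len(pos))
    return pos, col


def _ply_colors_fallback(path: str, n: int) -> np.ndarray | None:
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"end_header\n"):
            chunk = fh.readline()
            if not chunk:
                return None
            header += chunk
    if b"property uchar red" not in header:
        return None
    return np.full((n, 3), 128, dtype=np.uint8)


def _read_pcd(path: str) -> tuple[np.ndarray, np.ndarray | None]:
    """ASCII PCD with FIELDS x y z [rgb]; rgb packed as a float (PCL style)."""
    fields: list[str] = []
    n_expected = None
    data_lines: list[str] = []
    in_data = False
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                data_lines.append(line)
                continue
            key, _, rest = line.partition(" ")
            key = key.upper()
            if key == "FIELDS":
                fields = rest.split()
            elif key == "POINTS":
                n_expected = int(rest)
            elif key == "DATA":
                if rest.strip() != "ascii":
                    raise CloudFormatError(
                        f"{path}:{lineno}: only ASCII PCD data is supported"
                    )
                in_data = True
    if not fields or not {"x", "y", "z"} <= set(fields):
        raise CloudFormatError(f"{path}: PCD header lacks x y z FIELDS")
    try:
        arr = np.loadtxt(_io.StringIO("\n".join(data_lines)), ndmin=2)
    except ValueError as exc:
        raise CloudFormatError(f"{path}: PCD data parse failed ({exc})") from exc
    if arr.shape[1] != len(fields):
        raise CloudFormatError(
            f"{path}: PCD records have {arr.shape[1]} columns, header names "
            f"{len(fields)} fields"
        )
    if n_expected is not None and len(arr) != n_expected:
        raise CloudFormatError(
            f"{path}: POINTS says {n_expected} but {len(arr)} records found"
        )
    ix = [fields.index(a) for a in ("x", "y", "z")]
    pos = arr[:, ix]
    col = None
    if "rgb" in fields:
        packed = arr[:, fields.index("rgb")].astype(np.float32)
        raw = packed.view(np.uint32)
        col = np.stack(
            [(raw >> 16) & 255, (raw >> 8) & 255, raw & 255], axis=1
        ).astype(np.uint8)
    return pos, col


def _write_pcd(cloud: ColoredPointCloud, path: str) -> None:
    rgb = cloud.colors.astype(np.uint32)
    packed = (rgb[:, 0] << 16) | (rgb[:, 1] << 8) | rgb[:, 2]
    as_float = packed.astype(np.uint32).view(np.float32)
    n = cloud.n
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\nFIELDS x y z rgb\nSIZE 4 4 4 4\nTYPE F F F F\n"
            f"COUNT 1 1 1 1\nWIDTH {n}\nHEIGHT 1\n"
            f"VIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
        )
        for p, c in zip(cloud.positions.astype(np.float32), as_float):
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g} {c:.9g}\n")


def _read_xyzrgb(path: str) -> tuple[np.ndarray, np.ndarray | None]:
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise CloudFormatError(f"{path}: text parse failed ({exc})") from exc
    if arr.size == 0:
        raise CloudFormatError(f"{path}: empty file")
    if arr.shape[1] == 3:
        return arr, None
    if arr.shape[1] >= 6:
        return arr[:, :3], np.clip(arr[:, 3:6], 0, 255).astype(np.uint8)
    raise CloudFormatError(
        f"{path}: expected 3 (xyz) or 6 (xyzrgb) columns, got {arr.shape[1]}"
    )


def bbox_diagonal(cloud: ColoredPointCloud | np.ndarray) -> float:
    """Length of the axis-aligned bounding-box main diagonal (0 for 1 point)."""
    pos = cloud.positions if isinstance(cloud, ColoredPointCloud) else np.asarray(cloud)
    if len(pos) < 1:
        raise ValueError("empty cloud")
    return float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))


def _voxel_subsample_indices(pos: np.ndarray, voxel: float) -> np.ndarray:
    """Index of the point nearest its occupied voxel centroid, per voxel."""
    keys = np.floor((pos - pos.min(axis=0)) / voxel).astype(np.int64)
    order = np.lexsort(keys.T)
    keys_sorted = keys[order]
    boundaries = np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)
    starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(pos)]])
    keep = np.empty(len(starts) - 1, dtype=np.int64)
    for v, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
        idx = order[a:b]
        pts = pos[idx]
        centroid = pts.mean(axis=0)
        keep[v] = idx[np.argmin(((pts - centroid) ** 2).sum(axis=1))]
    return np.sort(keep)


def uniform_simplify(cloud: ColoredPointCloud, target_n: int,
                     tol: float = 0.1, max_bisect: int = 40) -> ColoredPointCloud:
    """Uniform density reduction to about ``target_n`` points.

    Voxel-grid subsampling keeping, per occupied voxel, the original point
    nearest the voxel centroid (no interpolation: colors survive
    bit-exactly). The voxel size is bisected until the output count falls
    within ``target_n`` (1 ± tol). Clouds already at or below the target
    are returned unchanged.
    """
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if cloud.n <= target_n:
        return cloud
    diag = bbox_diagonal(cloud)
    if diag == 0:  # all points coincide; any single representative is uniform
        return cloud.select(np.array([0]))
    lo, hi = 1e-6 * diag, diag
    best = None
    for _ in range(max_bisect):
        voxel = 0.5 * (lo + hi)
        keep = _voxel_subsample_indices(cloud.positions, voxel)
        m = len(keep)
        if best is None or abs(m - target_n) < abs(len(best) - target_n):
            best = keep
        if m > target_n * (1 + tol):
            lo = voxel
        elif m < target_n * (1 - tol):
            hi = voxel
        else:
            best = keep
            break
    return cloud.select(best)
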