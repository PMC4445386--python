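"""Data model and I/O for soma point clouds, image volumes and layer meshes.

Coordinate convention (shared by the whole package)
---------------------------------------------------
Coordinates are 0-based voxel units ``(x, y, z)``.  A :class:`VolumeImage`
stores its intensity grid as a C-ordered numpy array indexed ``data[z, y, x]``
so that ``x`` is the fastest-varying storage axis (one TIFF page per z plane).
Physical position is ``index * voxel_size_um``; the default voxel size is
1 µm, so voxel units and micrometres coincide unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass(frozen=True)
class SomaPoint:
    """A single detected or simulated soma center."""

    id: int
    x: float
    y: float
    z: float
    intensity: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"point id must be >= 0, got {self.id}")
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"point {self.id} has non-finite coordinates")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"point {self.id} has negative intensity")


class PointCloud:
    """An ordered collection of soma centers.

    Parameters
    ----------
    xyz:
        ``(n, 3)`` array of coordinates in voxel units.
    ids:
        Unique non-negative integer ids, one per point.  Assigned from row
        order when omitted.
    intensity:
        Optional per-point gray value.
    label:
        Optional per-point free-text tag.
    extras:
        Optional named float columns (e.g. ``mass``, ``manifold_distance``)
        carried through save/load round trips.
    voxel_size_um:
        Physical edge length of a voxel in micrometres (default 1.0).
    """

    def __init__(
        self,
        xyz: np.ndarray,
        ids: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
        label: Sequence[str] | None = None,
        extras: dict[str, np.ndarray] | None = None,
        voxel_size_um: float = 1.0,
        provenance: str = "",
    ) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if xyz.size and not np.all(np.isfinite(xyz)):
            raise ValueError("point coordinates must be finite")
        n = len(xyz)
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        else:
            ids = np.asarray(ids, dtype=np.int64)
            if len(ids) != n:
                raise ValueError("ids and xyz length mismatch")
            if np.any(ids < 0):
                raise ValueError("ids must be >= 0")
            if len(np.unique(ids)) != n:
                raise ValueError("duplicate point ids")
        if intensity is not None:
            intensity = np.asarray(intensity, dtype=float)
            if len(intensity) != n:
                raise ValueError("intensity length mismatch")
        if label is not None and len(label) != n:
            raise ValueError("label length mismatch")
        if voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.xyz = xyz
        self.ids = ids
        self.intensity = intensity
        self.label = list(label) if label is not None else None
        self.extras = {k: np.asarray(v, dtype=float) for k, v in (extras or {}).items()}
        for k, v in self.extras.items():
            if len(v) != n:
                raise ValueError(f"extra column {k!r} length mismatch")
        self.voxel_size_um = float(voxel_size_um)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.xyz)

    def __iter__(self) -> Iterator[SomaPoint]:
        for i in range(len(self)):
            yield SomaPoint(
                id=int(self.ids[i]),
                x=float(self.xyz[i, 0]),
                y=float(self.xyz[i, 1]),
                z=float(self.xyz[i, 2]),
                intensity=None if self.intensity is None else float(self.intensity[i]),
                label=None if self.label is None else self.label[i],
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PointCloud):
            return NotImplemented
        if len(self) != len(other):
            return False
        same = np.array_equal(self.ids, other.ids) and np.allclose(
            self.xyz, other.xyz, atol=0, rtol=0
        )
        if not same:
            return False
        if (self.intensity is None) != (other.intensity is None):
            return False
        if self.intensity is not None and not np.allclose(
            self.intensity, other.intensity, atol=0, rtol=0
        ):
            return False
        return self.label == other.label

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to ``mask`` (bool or index array)."""
        mask = np.asarray(mask)
        return PointCloud(
            self.xyz[mask],
            ids=self.ids[mask],
            intensity=None if self.intensity is None else self.intensity[mask],
            label=None
            if self.label is None
            else [self.label[i] for i in np.arange(len(self))[mask]]
            if mask.dtype == bool
            else [self.label[i] for i in mask],
            extras={k: v[mask] for k, v in self.extras.items()},
            voxel_size_um=self.voxel_size_um,
            provenance=self.provenance,
        )


class VolumeImage:
    """A 3D intensity grid with voxel-size metadata.

    ``data`` is indexed ``[z, y, x]``; :attr:`dims` reports ``(X, Y, Z)``.
    """

    def __init__(self, data: np.ndarray, voxel_size_um: float = 1.0) -> None:
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        if data.dtype not in (np.uint8, np.uint16):
            raise FormatError(f"unsupported dtype {data.dtype}; expected uint8/uint16")
        if min(data.shape) < 1:
            raise ValueError("all volume dims must be >= 1")
        if voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.data = data
        self.voxel_size_um = float(voxel_size_um)

    @property
    def dims(self) -> tuple[int, int, int]:
        """Volume extent as ``(X, Y, Z)``."""
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    def __getitem__(self, key):
        return self.data[key]


@dataclass
class Mesh3D:
    """A triangle mesh with an optional per-face scalar (e.g. gap area)."""

    vertices: np.ndarray
    faces: np.ndarray
    face_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of vertex range")
            degen = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degen.any():
                raise ValueError("degenerate face (repeated vertex index)")
        if self.face_scalar is not None:
            self.face_scalar = np.asarray(self.face_scalar, dtype=float)
            if len(self.face_scalar) != len(self.faces):
                raise ValueError("face_scalar length mismatch")


# ---------------------------------------------------------------------------
# point cloud I/O

_CANONICAL_COLUMNS = ("x", "y", "z", "intensity", "label")


def load_point_cloud(path: str | Path, dialect: str = "csv") -> PointCloud:
    """Read a delimited soma point cloud.

    ``dialect="csv"`` expects comma-separated columns with an optional header
    (auto-detected); ``dialect="marker"`` is the same layout with the header
    forbidden.  The first three numeric columns are x, y, z; a fourth numeric
    column (or a column named ``intensity``) carries the gray value.  Lines
    starting with ``#`` are treated as comments and stashed in ``provenance``.
    """
    if dialect not in ("csv", "marker"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    comments: list[str] = []
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            comments.append(stripped.lstrip("# "))
            continue
        rows.append((lineno, [tok.strip() for tok in stripped.split(",")]))

    if not rows:
        warnings.warn(f"{path}: no data rows, returning empty cloud", stacklevel=2)
        return PointCloud(np.empty((0, 3)), provenance="\n".join(comments))

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header: list[str] | None = None
    first_toks = rows[0][1]
    if dialect == "csv" and not all(_is_number(t) for t in first_toks[:3]):
        header = [t.lower() for t in first_toks]
        rows = rows[1:]
        if not rows:
            warnings.warn(f"{path}: header only, returning empty cloud", stacklevel=2)
            return PointCloud(np.empty((0, 3)), provenance="\n".join(comments))

    if header is not None:
        try:
            cidx = {name: header.index(name) for name in header}
            xi, yi, zi = cidx["x"], cidx["y"], cidx["z"]
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: header must name x,y,z columns: {header}") from exc
        ii = cidx.get("intensity")
        li = cidx.get("label")
        idi = cidx.get("id")
        extra_names = [
            h for h in header if h not in ("id", "x", "y", "z", "intensity", "label")
        ]
    else:
        xi, yi, zi = 0, 1, 2
        ncols = len(rows[0][1])
        ii = 3 if ncols >= 4 else None
        li = 4 if ncols >= 5 else None
        idi = None
        extra_names = []

    xyz = np.empty((len(rows), 3))
    inten = np.empty(len(rows)) if ii is not None else None
    labels = [] if li is not None else None
    ids = np.empty(len(rows), dtype=np.int64) if idi is not None else None
    extras = {name: np.empty(len(rows)) for name in extra_names}
    for r, (lineno, toks) in enumerate(rows):
        try:
            xyz[r] = (float(toks[xi]), float(toks[yi]), float(toks[zi]))
            if inten is not None:
                inten[r] = float(toks[ii])
            if ids is not None:
                ids[r] = int(float(toks[idi]))
            for name in extra_names:
                extras[name][r] = float(toks[header.index(name)])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed row at line {lineno}: {toks}") from exc
        if labels is not None:
            labels.append(toks[li] if li < len(toks) else "")
    return PointCloud(
        xyz,
        ids=ids,
        intensity=inten,
        label=labels,
        extras=extras,
        provenance="\n".join(comments),
    )


def save_point_cloud(
    cloud: PointCloud, path: str | Path, comment: str | None = None
) -> None:
    """Write a cloud as CSV with header ``x,y,z[,intensity,label,...]``.

    Numeric values use fixed 6-decimal precision; row order equals point
    order, so save -> load -> save is byte-identical.  An optional ``comment``
    (e.g. a config hash) is written as a leading ``#`` line.
    """
    path = Path(path)
    cols = ["x", "y", "z"]
    if cloud.intensity is not None:
        cols.append("intensity")
    if cloud.label is not None:
        cols.append("label")
    extra_names = sorted(cloud.extras)
    cols.extend(extra_names)
    lines = []
    if comment:
        lines.append("# " + comment.replace("\n", " "))
    lines.append(",".join(cols))
    for i in range(len(cloud)):
        row = [f"{v:.6f}" for v in cloud.xyz[i]]
        if cloud.intensity is not None:
            row.append(f"{cloud.intensity[i]:.6f}")
        if cloud.label is not None:
            row.append(str(cloud.label[i]))
        for name in extra_names:
            row.append(f"{cloud.extras[name][i]:.6f}")
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# volume I/O


def load_volume(path: str | Path, voxel_size_um: float = 1.0) -> VolumeImage:
    """Read a multipage TIFF as a volume (one z plane per page)."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several exception types
        raise FormatError(f"{path}: cannot read TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3 or data.dtype == object:
        raise FormatError(f"{path}: expected uniform multipage TIFF, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: unsupported dtype {data.dtype}")
    return VolumeImage(data, voxel_size_um=voxel_size_um)


def save_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as a multipage TIFF, one page per z plane."""
    # explicit photometric: 3- or 4-plane stacks must not be guessed as RGB
    tifffile.imwrite(Path(path), volume.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# mesh export


def _scalar_to_rgb(values: np.ndarray) -> np.ndarray:
    """Map scalars monotonically onto a blue (small) -> red (large) ramp."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    t = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    rgb = np.empty((len(v), 3), dtype=np.uint8)
    rgb[:, 0] = np.round(255 * t)
    rgb[:, 1] = np.round(64 * (1 - np.abs(2 * t - 1)))
    rgb[:, 2] = np.round(255 * (1 - t))
    return rgb


def export_mesh_ply(mesh: Mesh3D, path: str | Path, comment: str | None = None) -> None:
    """Write an ASCII PLY 1.0 file.

    When ``face_scalar`` is present it is stored as a per-face ``quality``
    property and additionally mapped to uchar RGB (larger values toward red).
    """
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise ValueError("cannot export an empty mesh")
    path = Path(path)
    has_scalar = mesh.face_scalar is not None
    header = ["ply", "format ascii 1.0"]
    if comment:
        header.append("comment " + comment.replace("\n", " "))
    header += [
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
    ]
    if has_scalar:
        header += [
            "property float quality",
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    header.append("end_header")
    lines = list(header)
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    rgb = _scalar_to_rgb(mesh.face_scalar) if has_scalar else None
    for i, f in enumerate(mesh.faces):
        row = f"3 {f[0]} {f[1]} {f[2]}"
        if has_scalar:
            r, g, b = rgb[i]
            row += f" {mesh.face_scalar[i]:.6f} {r} {g} {b}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
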