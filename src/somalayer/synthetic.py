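"""Ground-truthed synthetic inputs: folded cell-layer clouds and soma volumes.

The layer generator emulates a sheet of cell bodies one cell thick lying on a
folded 2D surface (folds model cortical folia).  Cells sit on a jittered
hexagonal lattice in the surface's intrinsic (u, v) coordinates; circular
"gaps" are emptied of cells and a configurable fraction of off-layer false
positives (modelling labelled neurite fragments) is added at a normal offset.
The fold is a developable sinusoidal extrusion, i.e. an exact isometry of the
plane, so geodesic-preserving 2D embeddings of the generated charts exist.

The volume generator plants bright spheres (somata) on a noisy background
with optional curvilinear clutter (neurite-like filaments) and returns the
exact centers so every localization stage can be scored without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import PointCloud, VolumeImage


@dataclass
class LayerSpec:
    """Parameters of a synthetic folded cell layer.

    ``extent_um`` is the intrinsic (u, v) size of the sheet; ``fold_*``
    define a sinusoidal fold along u (amplitude 0 = flat plane);
    ``cell_spacing_um`` is the hexagonal lattice pitch (approximately the
    mean nearest-neighbour spacing); ``jitter_um`` is isotropic positional
    noise; ``gaps`` lists ``(u, v, radius)`` discs to empty; false positives
    are placed at a normal offset drawn uniformly from ``fp_offset_um``.
    """

    extent_um: tuple[float, float] = (600.0, 600.0)
    fold_amplitude_um: float = 80.0
    fold_wavelength_um: float = 400.0
    cell_spacing_um: float = 12.0
    jitter_um: float = 1.5
    gaps: list[tuple[float, float, float]] = field(default_factory=list)
    fp_fraction: float = 0.0
    fp_offset_um: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_spacing_um <= 0:
            raise ValueError("cell_spacing_um must be positive")
        if not (0 <= self.fp_fraction < 1):
            raise ValueError("fp_fraction must be in [0, 1)")
        w, d = self.extent_um
        for (gu, gv, gr) in self.gaps:
            if not (0 <= gu <= w and 0 <= gv <= d):
                raise ValueError(f"gap center ({gu},{gv}) outside extent {self.extent_um}")
            if gr <= 0:
                raise ValueError("gap radius must be positive")


@dataclass
class FoldedLayer:
    """A generated layer cloud with its ground truth."""

    cloud: PointCloud
    is_fp: np.ndarray  # bool per point
    gaps: list[tuple[float, float, float]]
    uv: np.ndarray  # true intrinsic coordinates per point (FPs: surface foot)


@dataclass
class VolumeSpec:
    """Parameters of a synthetic soma image volume."""

    dims: tuple[int, int, int] = (128, 128, 128)
    n_somata: int = 20
    soma_radius_vox: float = 6.0
    min_separation_vox: float = 15.0
    peak_intensity: float = 200.0
    background: float = 10.0
    noise_sigma: float = 10.0
    clutter: int = 0
    dtype: str = "uint8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_radius_vox <= 0 or self.min_separation_vox <= 0:
            raise ValueError("radii must be positive")
        if self.n_somata < 0:
            raise ValueError("n_somata must be >= 0")
        if self.dtype not in ("uint8", "uint16"):
            raise ValueError("dtype must be uint8 or uint16")


# ---------------------------------------------------------------------------
# folded layer


def _fold_profile(spec: LayerSpec, n_samples: int = 20001):
    """Arc-length parameterisation of the fold profile x -> (x, A sin(2πx/λ)).

    Returns interpolators mapping intrinsic u (arc length) to x and giving the
    profile height/tangent, so the (u, v) -> 3D map is an exact isometry.
    """
    A = spec.fold_amplitude_um
    lam = spec.fold_wavelength_um
    width = spec.extent_um[0]
    if A == 0:
        xs = np.linspace(0, width, 2)
        s = xs.copy()
        return xs, s

    # dense x grid generously covering the arc length `width`
    x_max = width * 1.05 + lam
    xs = np.linspace(0.0, x_max, n_samples)
    dz = A * (2 * np.pi / lam) * np.cos(2 * np.pi * xs / lam)
    ds = np.sqrt(1.0 + dz**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xs))])
    return xs, s


def _embed_uv(spec: LayerSpec, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map intrinsic (u, v) to 3D surface points and unit normals."""
    A = spec.fold_amplitude_um
    lam = spec.fold_wavelength_um
    if A == 0:
        pts = np.column_stack([uv[:, 0], uv[:, 1], np.zeros(len(uv))])
        normals = np.tile([0.0, 0.0, 1.0], (len(uv), 1))
        return pts, normals
    xs, s = _fold_profile(spec)
    x = np.interp(uv[:, 0], s, xs)
    z = A * np.sin(2 * np.pi * x / lam)
    dzdx = A * (2 * np.pi / lam) * np.cos(2 * np.pi * x / lam)
    inv_norm = 1.0 / np.sqrt(1.0 + dzdx**2)
    pts = np.column_stack([x, uv[:, 1], z])
    normals = np.column_stack([-dzdx * inv_norm, np.zeros(len(uv)), inv_norm])
    return pts, normals


def _hex_lattice(extent: tuple[float, float], pitch: float) -> np.ndarray:
    """Hexagonal lattice points covering [0, w] x [0, d] at the given pitch."""
    w, d = extent
    row_step = pitch * np.sqrt(3.0) / 2.0
    rows = int(np.floor(d / row_step)) + 1
    pts = []
    for r in range(rows):
        v = r * row_step
        offset = (pitch / 2.0) if (r % 2) else 0.0
        us = np.arange(offset, w + 1e-9, pitch)
        pts.append(np.column_stack([us, np.full(len(us), v)]))
    return np.concatenate(pts) if pts else np.empty((0, 2))


def generate_folded_layer(spec: LayerSpec) -> FoldedLayer:
    """Generate a folded-sheet soma cloud with planted gaps and off-layer FPs.

    Deterministic given ``spec.seed``.  Coordinates are voxel units at
    1 µm/voxel.  Raises if the spacing is too large to place any cell.
    """
    rng = np.random.default_rng(spec.seed)
    uv = _hex_lattice(spec.extent_um, spec.cell_spacing_um)
    if len(uv) < 3 or spec.cell_spacing_um > min(spec.extent_um):
        raise ValueError("cell spacing too large for the extent: no usable layer")

    # empty the planted gap discs in intrinsic coordinates
    keep = np.ones(len(uv), dtype=bool)
    for (gu, gv, gr) in spec.gaps:
        keep &= (uv[:, 0] - gu) ** 2 + (uv[:, 1] - gv) ** 2 > gr**2
    uv = uv[keep]
    if len(uv) == 0:
        raise ValueError("gap discs removed every cell")

    pts3d, normals = _embed_uv(spec, uv)
    # isotropic positional jitter: in-plane (u, v) and along the normal
    tang_u = np.zeros_like(pts3d)
    if spec.fold_amplitude_um == 0:
        tang_u[:, 0] = 1.0
    else:
        tang_u[:, 0] = normals[:, 2]
        tang_u[:, 2] = -normals[:, 0]
    tang_v = np.tile([0.0, 1.0, 0.0], (len(uv), 1))
    j = rng.normal(0.0, spec.jitter_um, size=(len(uv), 3))
    pts3d = pts3d + j[:, :1] * tang_u + j[:, 1:2] * tang_v + j[:, 2:3] * normals

    n_true = len(uv)
    n_fp = int(round(n_true * spec.fp_fraction / (1.0 - spec.fp_fraction)))
    if n_fp > 0:
        fp_uv = np.column_stack(
            [
                rng.uniform(0, spec.extent_um[0], n_fp),
                rng.uniform(0, spec.extent_um[1], n_fp),
            ]
        )
        fp_pts, fp_normals = _embed_uv(spec, fp_uv)
        off = rng.uniform(spec.fp_offset_um[0], spec.fp_offset_um[1], n_fp)
        off *= rng.choice([-1.0, 1.0], n_fp)
        fp_pts = fp_pts + off[:, None] * fp_normals
        xyz = np.vstack([pts3d, fp_pts])
        uv_all = np.vstack([uv, fp_uv])
        is_fp = np.concatenate([np.zeros(n_true, bool), np.ones(n_fp, bool)])
    else:
        xyz, uv_all, is_fp = pts3d, uv, np.zeros(n_true, bool)

    # shuffle so downstream code cannot rely on generation order
    order = rng.permutation(len(xyz))
    xyz, uv_all, is_fp = xyz[order], uv_all[order], is_fp[order]

    cloud = PointCloud(
        xyz,
        voxel_size_um=1.0,
        provenance=f"synthetic folded layer seed={spec.seed} spacing={spec.cell_spacing_um}",
    )
    return FoldedLayer(cloud=cloud, is_fp=is_fp, gaps=list(spec.gaps), uv=uv_all)


# ---------------------------------------------------------------------------
# soma volume


def _place_centers(spec: VolumeSpec, rng: np.random.Generator) -> np.ndarray:
    margin = spec.soma_radius_vox + 1.0
    lo = np.full(3, margin)
    hi = np.array(spec.dims, dtype=float) - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the soma radius")
    centers: list[np.ndarray] = []
    max_tries = 10000 * max(spec.n_somata, 1)
    tries = 0
    while len(centers) < spec.n_somata:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {spec.n_somata} somata at separation "
                f"{spec.min_separation_vox} in dims {spec.dims}"
            )
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) >= spec.min_separation_vox for p in centers):
            centers.append(c)
    return np.array(centers).reshape(-1, 3)


def _draw_sphere(vol: np.ndarray, center: np.ndarray, radius: float, peak: float,
                 background: float) -> None:
    """Add a sphere with a soft 1-voxel edge: peak inside, background outside."""
    cx, cy, cz = center
    r_out = radius + 0.5
    nz, ny, nx = vol.shape
    x0, x1 = max(0, int(np.floor(cx - r_out))), min(nx, int(np.ceil(cx + r_out)) + 1)
    y0, y1 = max(0, int(np.floor(cy - r_out))), min(ny, int(np.ceil(cy + r_out)) + 1)
    z0, z1 = max(0, int(np.floor(cz - r_out))), min(nz, int(np.ceil(cz + r_out)) + 1)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
    frac = np.clip(radius + 0.5 - dist, 0.0, 1.0)  # 1 inside, 0 beyond r+0.5
    patch = vol[z0:z1, y0:y1, x0:x1]
    np.maximum(patch, background + (peak - background) * frac, out=patch)


def _draw_filament(vol: np.ndarray, rng: np.random.Generator, intensity: float,
                   background: float) -> None:
    """Add a bright quadratic-Bezier filament of ~1 voxel radius."""
    dims_zyx = np.array(vol.shape, dtype=float)
    p = rng.uniform(0, dims_zyx, size=(3, 3))
    t = np.linspace(0, 1, 400)[:, None]
    curve = ((1 - t) ** 2) * p[0] + 2 * t * (1 - t) * p[1] + (t**2) * p[2]
    idx = np.round(curve).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    idx = idx[ok]
    for dz, dy, dx in ((0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)):
        j = idx + np.array([dz, dy, dx])
        ok = np.all((j >= 0) & (j < np.array(vol.shape)), axis=1)
        j = j[ok]
        vol[j[:, 0], j[:, 1], j[:, 2]] = np.maximum(
            vol[j[:, 0], j[:, 1], j[:, 2]], intensity
        )


def generate_soma_volume(spec: VolumeSpec) -> tuple[VolumeImage, np.ndarray]:
    """Generate a soma volume and return ``(volume, true centers (n, 3) xyz)``.

    Somata are spheres of ``soma_radius_vox`` with a soft 1-voxel edge at
    ``peak_intensity`` on a flat ``background``, pairwise separated by at
    least ``min_separation_vox``; ``clutter`` filaments and Gaussian noise
    are added on top, and the result is clipped to the dtype range.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    nx, ny, nz = spec.dims
    vol = np.full((nz, ny, nx), spec.background, dtype=float)
    for c in centers:
        _draw_sphere(vol, c, spec.soma_radius_vox, spec.peak_intensity, spec.background)
    for _ in range(spec.clutter):
        _draw_filament(vol, rng, 0.5 * spec.peak_intensity, spec.background)
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, vol.shape)
    info = np.iinfo(np.uint8 if spec.dtype == "uint8" else np.uint16)
    vol = np.clip(np.round(vol), info.min, info.max).astype(spec.dtype)
    return VolumeImage(vol, voxel_size_um=1.0), centers
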