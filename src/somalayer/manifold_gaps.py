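"""Gap detection in a folded 2D cell layer.

A layer point cloud is sliced into overlapping charts, each chart is unfolded
to 2D with Isomap (geodesic multidimensional scaling), triangulated with
Delaunay, stripped of boundary artifacts, and then — from every triangle — a
maximal *empty convex region* is grown by adding adjacent triangles while
the merged boundary polygon stays convex.  Because regions are unions of
triangles of a triangulation of the cells, their interiors contain no cell:
the grown area around a triangle measures the local rarefaction ("gap") of
the layer.  Pooled per-cell areas are summarised by a log-normal fit.

All areas are reported in µm² of the unfolded (intrinsic) surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .core_io import Mesh3D, PointCloud


class ChartDisconnectedError(ValueError):
    """Neighbour graph of a chart is disconnected (cannot be embedded)."""

    def __init__(self, n_components: int, largest: np.ndarray):
        self.n_components = n_components
        self.largest_component = largest
        super().__init__(
            f"chart neighbour graph has {n_components} components; "
            f"largest has {len(largest)} members — split the chart first"
        )


@dataclass
class GapParams:
    """Parameters of chart unfolding and gap growth.

    ``perimeter_factor`` scales the median triangulation edge length to form
    the boundary-pruning threshold (set ``perimeter_absolute`` to override
    with a fixed length); ``convexity_tol_deg`` absorbs floating-point noise
    in the convexity test; slice geometry is in voxels.
    """

    isomap_neighbors: int = 10
    embed_dim: int = 2
    perimeter_factor: float = 4.0
    perimeter_absolute: float | None = None
    convexity_tol_deg: float = 1.0
    slice_height: float = 2000.0
    slice_overlap: float = 120.0
    refine_iters: int = 1500
    refine_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.embed_dim != 2:
            raise ValueError("embed_dim must be 2")
        for name in ("isomap_neighbors", "perimeter_factor", "convexity_tol_deg",
                     "slice_height", "slice_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.slice_overlap >= self.slice_height:
            raise ValueError("slice_overlap must be smaller than slice_height")


@dataclass
class Chart:
    """A patch of the layer: member ids, 3D coords (µm), optional 2D embedding."""

    member_ids: np.ndarray
    coords3d: np.ndarray
    coords2d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.member_ids = np.asarray(self.member_ids, dtype=np.int64)
        self.coords3d = np.asarray(self.coords3d, dtype=float).reshape(-1, 3)
        if len(self.member_ids) != len(self.coords3d):
            raise ValueError("member_ids and coords3d length mismatch")
        if len(np.unique(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate member ids in chart")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Triangulation2D:
    """A 2D triangulation with shared-edge adjacency and boundary flags."""

    vertices: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3) CCW
    adjacency: list[np.ndarray] = field(default_factory=list)
    boundary_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if not self.adjacency:
            self.adjacency, self.boundary_flags = _build_adjacency(self.triangles)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.abs(_cross2(b - a, c - a))

    def triangle_perimeters(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return (
            np.linalg.norm(a - b, axis=1)
            + np.linalg.norm(b - c, axis=1)
            + np.linalg.norm(c - a, axis=1)
        )

    def edge_lengths(self) -> np.ndarray:
        edges = set()
        for t in self.triangles:
            for i, j in ((0, 1), (1, 2), (0, 2)):
                edges.add((min(t[i], t[j]), max(t[i], t[j])))
        e = np.array(sorted(edges))
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)


@dataclass
class ConvexRegion:
    """An empty convex union of triangles grown around a seed triangle."""

    seed_triangle: int
    triangle_ids: frozenset[int]
    boundary_polygon: np.ndarray  # ordered vertex ids, CCW
    area_um2: float


@dataclass
class LogNormalFit:
    """Maximum-likelihood log-normal parameters with 99% confidence intervals."""

    mu: float
    sigma: float
    ci99_mu: tuple[float, float]
    ci99_sigma: tuple[float, float]
    n: int


# ---------------------------------------------------------------------------
# slicing


_AXIS = {"x": 0, "y": 1, "z": 2}


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z component of the cross product of stacked 2D vectors."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def slice_cloud(
    cloud: PointCloud, axis: str, height: float, overlap: float
) -> list[Chart]:
    """Cut a cloud into overlapping slabs perpendicular to ``axis``.

    Consecutive half-open intervals of width ``height`` step by
    ``height - overlap`` (voxel units) from the cloud's minimum coordinate;
    the last interval is closed above so the full extent is covered.  Points
    inside an overlap zone belong to exactly two charts.  Chart coordinates
    are converted to µm.
    """
    if overlap >= height:
        raise ValueError("overlap must be smaller than height")
    if len(cloud) == 0:
        return []
    ax = _AXIS[axis]
    coord = cloud.xyz[:, ax]
    lo, hi = float(coord.min()), float(coord.max())
    extent = hi - lo
    step = height - overlap
    n_slices = max(1, int(np.ceil((extent - height) / step)) + 1) if extent > height else 1
    charts = []
    for i in range(n_slices):
        start = lo + i * step
        last = i == n_slices - 1
        if last:
            mask = (coord >= start) & (coord <= start + height)
        else:
            mask = (coord >= start) & (coord < start + height)
        if not mask.any():
            continue
        charts.append(
            Chart(
                member_ids=cloud.ids[mask],
                coords3d=cloud.xyz[mask] * cloud.voxel_size_um,
            )
        )
    return charts


# ---------------------------------------------------------------------------
# Isomap unfolding


def _local_stress_refine(
    pts3d: np.ndarray, Y: np.ndarray, radius: float, iters: int
) -> np.ndarray:
    """Reduce the systematic overshoot of graph shortest paths.

    Shortest paths through a kNN graph zig-zag between samples, so Isomap
    distances overestimate geodesics by a few percent.  On a layer whose
    extrinsic curvature radius is large compared to the cell spacing, 3D
    chord lengths between *nearby* cells equal intrinsic geodesics almost
    exactly, so we polish the embedding by stress majorization (Guttman
    transform) against all chords shorter than ``radius``, starting from the
    Isomap solution.  Stops early once the layout is stationary.
    """
    tree = cKDTree(pts3d)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return Y
    d = np.linalg.norm(pts3d[pairs[:, 0]] - pts3d[pairs[:, 1]], axis=1)
    n = len(Y)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    dd = np.concatenate([d, d])
    deg = np.bincount(src, minlength=n).astype(float)
    deg[deg == 0] = 1.0
    X = Y.copy()
    scale = float(np.linalg.norm(Y.max(axis=0) - Y.min(axis=0))) or 1.0
    for _ in range(iters):
        diff = X[src] - X[dst]
        norm = np.linalg.norm(diff, axis=1)
        norm[norm == 0] = 1e-12
        target = X[dst] + dd[:, None] * diff / norm[:, None]
        newX = np.zeros_like(X)
        np.add.at(newX, src, target)
        newX /= deg[:, None]
        move = float(np.abs(newX - X).max())
        X = newX
        if move < 1e-9 * scale:
            break
    return X


def isomap_embed(chart: Chart, params: GapParams) -> Chart:
    """Unfold a chart to 2D with Isomap (geodesic distances via shortest paths).

    The raw Isomap layout is polished by local stress majorization against
    3D chord lengths of nearby pairs (see :func:`_local_stress_refine`),
    then centered at the origin, rotated onto its principal axes and
    sign-fixed (each axis flipped so its skewness is positive; if the
    skewness vanishes, so that the first member's coordinate is
    non-negative).  Raises :class:`ChartDisconnectedError` when the
    ``isomap_neighbors``-NN graph is disconnected.
    """
    n = len(chart)
    if n < 3:
        raise ValueError("chart needs at least 3 members to embed and triangulate")
    k = min(params.isomap_neighbors, n - 1)
    graph = kneighbors_graph(chart.coords3d, n_neighbors=k, mode="distance")
    n_comp, comp = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        biggest = int(np.argmax(sizes))
        raise ChartDisconnectedError(n_comp, np.nonzero(comp == biggest)[0])

    iso = Isomap(n_neighbors=k, n_components=2, eigen_solver="dense")
    Y = iso.fit_transform(chart.coords3d)
    if params.refine_iters > 0:
        radius = params.refine_radius_factor * float(np.median(graph.data))
        Y = _local_stress_refine(chart.coords3d, Y, radius, params.refine_iters)
    Y = Y - Y.mean(axis=0)
    # rotate onto principal axes, then fix signs deterministically
    _, _, Vt = np.linalg.svd(Y, full_matrices=False)
    Y = Y @ Vt.T
    for col in range(2):
        c = Y[:, col]
        sd = c.std()
        skew = float(np.mean(c**3) / sd**3) if sd > 0 else 0.0
        if abs(skew) > 1e-9:
            if skew < 0:
                Y[:, col] = -c
        elif c[0] < 0:
            Y[:, col] = -c
    return Chart(member_ids=chart.member_ids, coords3d=chart.coords3d, coords2d=Y)


# ---------------------------------------------------------------------------
# locally weighted quadric residual


def lwr_distance(query: np.ndarray, neighbors: np.ndarray) -> float:
    """Distance (µm) from ``query`` to a locally weighted quadric surface fit.

    The neighbours' best-fit plane (by SVD) provides in-plane coordinates
    (a, b) and a height h; a quadric ``h ~ 1 + a + b + a² + ab + b²`` is fit
    with Gaussian weights of bandwidth equal to the median neighbour distance
    from the query.  Returns ``|h_query - h_predicted|`` — exact for points
    offset from a plane, second-order accurate on curved layers.
    """
    query = np.asarray(query, dtype=float).reshape(3)
    P = np.asarray(neighbors, dtype=float).reshape(-1, 3)
    if len(P) < 6:
        raise ValueError("need at least 6 neighbours for a quadric fit")
    center = P.mean(axis=0)
    Q = P - center
    _, S, Vt = np.linalg.svd(Q, full_matrices=False)
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) neighbourhood")
    e1, e2, nrm = Vt[0], Vt[1], Vt[2]
    a, b, h = Q @ e1, Q @ e2, Q @ nrm
    qc = query - center
    aq, bq, hq = qc @ e1, qc @ e2, qc @ nrm

    d = np.linalg.norm(P - query, axis=1)
    tau = float(np.median(d))
    if tau <= 0:
        tau = 1.0
    w = np.exp(-(d**2) / (2 * tau**2))
    A = np.column_stack([np.ones_like(a), a, b, a**2, a * b, b**2])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], h * sw, rcond=None)
    pred = float(
        np.array([1.0, aq, bq, aq**2, aq * bq, bq**2]) @ coef
    )
    return abs(float(hq) - pred)


# ---------------------------------------------------------------------------
# triangulation


def _build_adjacency(triangles: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    edge_map: dict[tuple[int, int], list[int]] = {}
    for ti, t in enumerate(triangles):
        for i, j in ((0, 1), (1, 2), (0, 2)):
            key = (min(t[i], t[j]), max(t[i], t[j]))
            edge_map.setdefault(key, []).append(ti)
    adj: list[set[int]] = [set() for _ in range(len(triangles))]
    boundary = np.zeros(len(triangles), dtype=bool)
    for tris in edge_map.values():
        if len(tris) == 2:
            a, b = tris
            adj[a].add(b)
            adj[b].add(a)
        elif len(tris) == 1:
            boundary[tris[0]] = True
    return [np.array(sorted(s), dtype=int) for s in adj], boundary


def delaunay_triangulate(chart: Chart) -> Triangulation2D:
    """Delaunay triangulation of a chart's 2D embedding.

    Triangles are oriented counter-clockwise; degenerate (zero-area)
    triangles are discarded.  Raises on collinear input.
    """
    if chart.coords2d is None:
        raise ValueError("chart has no 2D embedding; run isomap_embed first")
    pts = chart.coords2d
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        dt = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"cannot triangulate chart (collinear points?): {exc}") from exc
    tris = dt.simplices.copy()
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    signed = _cross2(b - a, c - a)
    flip = signed < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2], tris[flip, 1].copy()
    keep = np.abs(signed) > 0
    tris = tris[keep]
    if len(tris) == 0:
        raise ValueError("all triangles degenerate (collinear points)")
    return Triangulation2D(vertices=pts, triangles=tris)


def prune_boundary_triangles(tri: Triangulation2D, threshold: float) -> Triangulation2D:
    """Iteratively remove boundary triangles with perimeter above ``threshold``.

    Boundary flags are recomputed every round; interior triangles are only
    removed once exposed.  Idempotent at the fixed point; raises if pruning
    would delete every triangle.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    perim = tri.triangle_perimeters()
    alive = np.ones(tri.n_triangles, dtype=bool)
    while True:
        current = tri.triangles[alive]
        _, boundary = _build_adjacency(current)
        idx = np.nonzero(alive)[0]
        remove = idx[boundary & (perim[idx] > threshold)]
        if len(remove) == 0:
            break
        alive[remove] = False
        if not alive.any():
            raise ValueError("threshold too small: pruning removed all triangles")
    return Triangulation2D(vertices=tri.vertices, triangles=tri.triangles[alive])


# ---------------------------------------------------------------------------
# convex region growing


def _boundary_cycle(triangles: np.ndarray, member_ids: list[int]) -> np.ndarray | None:
    """Ordered boundary vertex cycle of a triangle union, or None if the
    boundary is not a single simple cycle (pinched or multiply connected)."""
    edge_count: dict[tuple[int, int], int] = {}
    for ti in member_ids:
        t = triangles[ti]
        for i, j in ((0, 1), (1, 2), (0, 2)):
            key = (min(t[i], t[j]), max(t[i], t[j]))
            edge_count[key] = edge_count.get(key, 0) + 1
    nbrs: dict[int, list[int]] = {}
    n_bedges = 0
    for (u, v), cnt in edge_count.items():
        if cnt == 1:
            n_bedges += 1
            nbrs.setdefault(u, []).append(v)
            nbrs.setdefault(v, []).append(u)
    if any(len(v) != 2 for v in nbrs.values()):
        return None
    # all member vertices must lie on the boundary (no interior vertex)
    member_vertices = set()
    for ti in member_ids:
        member_vertices.update(triangles[ti].tolist())
    if member_vertices != set(nbrs):
        return None
    start = min(nbrs)
    cycle = [start]
    prev, cur = None, start
    while True:
        a, b = nbrs[cur]
        nxt = a if a != prev else b
        if nxt == start:
            break
        cycle.append(nxt)
        prev, cur = cur, nxt
        if len(cycle) > n_bedges:
            return None
    if len(cycle) != n_bedges:
        return None  # more than one boundary loop
    return np.array(cycle, dtype=int)


def _is_convex(vertices: np.ndarray, cycle: np.ndarray, tol_deg: float) -> bool:
    """True iff the polygon is convex: every turn of the CCW cycle is a left
    turn within ``tol_deg`` slack."""
    pts = vertices[cycle]
    signed_area = 0.5 * float(
        np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    )
    if signed_area < 0:
        pts = pts[::-1]
    v = np.roll(pts, -1, axis=0) - pts
    cross = v[:, 0] * np.roll(v[:, 1], -1) - v[:, 1] * np.roll(v[:, 0], -1)
    dot = v[:, 0] * np.roll(v[:, 0], -1) + v[:, 1] * np.roll(v[:, 1], -1)
    turns = np.arctan2(cross, dot)
    return bool(np.all(turns >= -np.deg2rad(tol_deg)))


def grow_convex_region(
    tri: Triangulation2D, seed: int, tol: float = 1.0
) -> ConvexRegion:
    """Grow an empty convex region around ``seed`` by greedy BFS.

    Adjacent triangles are admitted iff the merged boundary polygon remains a
    single simple cycle, contains no triangulation vertex in its interior and
    stays convex within ``tol`` degrees.  Frontier candidates are examined in
    ascending triangle id, making the result deterministic; it is a lower
    bound on the maximal empty convex region containing the seed.
    """
    if not (0 <= seed < tri.n_triangles):
        raise ValueError(f"seed triangle {seed} out of range")
    areas = tri.triangle_areas()
    region: set[int] = {seed}
    cycle = _boundary_cycle(tri.triangles, [seed])

    def admissible(candidate: int) -> np.ndarray | None:
        trial = sorted(region | {candidate})
        c = _boundary_cycle(tri.triangles, trial)
        if c is None:
            return None
        if not _is_convex(tri.vertices, c, tol):
            return None
        return c

    frontier = set(tri.adjacency[seed].tolist())
    while frontier:
        next_frontier: set[int] = set()
        for cand in sorted(frontier):
            if cand in region:
                continue
            c = admissible(cand)
            if c is not None:
                region.add(cand)
                cycle = c
                next_frontier.update(tri.adjacency[cand].tolist())
        frontier = next_frontier - region
    return ConvexRegion(
        seed_triangle=seed,
        triangle_ids=frozenset(region),
        boundary_polygon=cycle,
        area_um2=float(areas[sorted(region)].sum()),
    )


# ---------------------------------------------------------------------------
# per-chart analysis


@dataclass
class ChartGapResult:
    """Per-triangle grown areas, per-cell largest tangent area, and the 3D mesh."""

    chart: Chart
    triangulation: Triangulation2D
    triangle_areas: np.ndarray  # grown convex-region area per triangle (µm²)
    cell_areas: dict[int, float]  # parent point id -> max incident grown area
    mesh: Mesh3D


def chart_gap_analysis(chart: Chart, params: GapParams) -> ChartGapResult:
    """Unfold, triangulate, prune and grow a convex region from every triangle.

    The per-cell statistic is the maximum grown area over the triangles
    incident to that cell ("largest convex polygon tangent to the cell");
    surviving triangles are lifted back to the chart's 3D coordinates with
    the grown area as per-face scalar.
    """
    if chart.coords2d is None:
        chart = isomap_embed(chart, params)
    tri = delaunay_triangulate(chart)
    threshold = (
        params.perimeter_absolute
        if params.perimeter_absolute is not None
        else params.perimeter_factor * float(np.median(tri.edge_lengths()))
    )
    tri = prune_boundary_triangles(tri, threshold)

    grown = np.empty(tri.n_triangles)
    for ti in range(tri.n_triangles):
        grown[ti] = grow_convex_region(tri, ti, tol=params.convexity_tol_deg).area_um2

    cell_areas: dict[int, float] = {}
    for ti, t in enumerate(tri.triangles):
        for v in t:
            pid = int(chart.member_ids[v])
            if grown[ti] > cell_areas.get(pid, -np.inf):
                cell_areas[pid] = float(grown[ti])

    mesh = Mesh3D(
        vertices=chart.coords3d,
        faces=tri.triangles,
        face_scalar=grown,
    )
    return ChartGapResult(
        chart=chart,
        triangulation=tri,
        triangle_areas=grown,
        cell_areas=cell_areas,
        mesh=mesh,
    )


# ---------------------------------------------------------------------------
# log-normal fit


def fit_lognormal(areas: np.ndarray) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of positive areas with 99% CIs.

    μ and σ are the mean and population (1/n) standard deviation of the log
    areas (the exact MLE); the μ interval uses normal theory, the σ interval
    the chi-square distribution with n−1 degrees of freedom.
    """
    a = np.asarray(areas, dtype=float).ravel()
    if len(a) < 2:
        raise ValueError("need at least 2 areas")
    if np.any(a <= 0):
        raise ValueError("areas must be strictly positive")
    logs = np.log(a)
    n = len(logs)
    mu = float(logs.mean())
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
    z = stats.norm.ppf(0.995)
    half = z * sigma / np.sqrt(n)
    ci_mu = (mu - half, mu + half)
    if sigma > 0:
        lo = sigma * np.sqrt(n / stats.chi2.ppf(0.995, n - 1))
        hi = sigma * np.sqrt(n / stats.chi2.ppf(0.005, n - 1))
        ci_sigma = (float(lo), float(hi))
    else:
        ci_sigma = (0.0, 0.0)
    return LogNormalFit(mu=mu, sigma=sigma, ci99_mu=ci_mu, ci99_sigma=ci_sigma, n=n)
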