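"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, sharing no
code path with the package implementation it checks.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# mutual-kNN clustering (O(n²) edge construction + union-find)


def brute_force_mutual_knn(xyz: np.ndarray, ids: np.ndarray, k: int):
    """Return (set of frozensets of member ids, set of isolated ids)."""
    n = len(xyz)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    knn = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (d[i, j], ids[j]))
        order = [j for j in order if j != i]
        knn.append(set(order[:k]))
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    degree = [0] * n
    for i in range(n):
        for j in knn[i]:
            if i in knn[j]:
                degree[i] += 1
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for i in range(n):
        if degree[i] > 0:
            comps.setdefault(find(i), []).append(i)
    clusters = {frozenset(int(ids[i]) for i in m) for m in comps.values()}
    isolated = {int(ids[i]) for i in range(n) if degree[i] == 0}
    return clusters, isolated


# ---------------------------------------------------------------------------
# two-level maximum-entropy thresholding (exhaustive)


def brute_force_max_entropy(hist) -> tuple[int, int]:
    p = [h / sum(hist) for h in hist]
    B = len(p)

    def entropy(lo, hi):  # bins [lo, hi] inclusive
        w = sum(p[lo : hi + 1])
        if w <= 0:
            return 0.0
        return -sum(pi / w * math.log(pi / w) for pi in p[lo : hi + 1] if pi > 0)

    def filled(lo, hi):
        return 1 if sum(p[lo : hi + 1]) > 0 else 0

    best, best_pair = (-1, -math.inf), None
    for t1 in range(B - 1):
        for t2 in range(t1 + 1, B):
            n = filled(0, t1) + filled(t1 + 1, t2) + filled(t2 + 1, B - 1)
            obj = entropy(0, t1) + entropy(t1 + 1, t2) + entropy(t2 + 1, B - 1)
            if (n, obj) > best:
                best, best_pair = (n, obj), (t1, t2)
    return best_pair


def exhaustive_max_entropy(hist) -> tuple[int, int]:
    """Exhaustive (all pairs) two-level maximum-entropy search using an
    interval entropy table; same objective as :func:`brute_force_max_entropy`
    but fast enough for 256-bin histograms."""
    h = np.asarray(hist, dtype=float)
    p = h / h.sum()
    B = len(p)
    cum_p = np.concatenate([[0.0], np.cumsum(p)])
    with np.errstate(divide="ignore", invalid="ignore"):
        plp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plp = np.concatenate([[0.0], np.cumsum(plp)])

    def interval(a, b):  # weight and entropy of bins [a, b]
        w = cum_p[b + 1] - cum_p[a]
        if w <= 0:
            return 0.0, 0.0
        s = cum_plp[b + 1] - cum_plp[a]
        return w, -(s / w - math.log(w))

    best, best_pair = (-1, -math.inf), None
    for t1 in range(B - 1):
        w1, e1 = interval(0, t1)
        for t2 in range(t1 + 1, B):
            w2, e2 = interval(t1 + 1, t2)
            w3, e3 = interval(t2 + 1, B - 1)
            key = ((w1 > 0) + (w2 > 0) + (w3 > 0), e1 + e2 + e3)
            if key > best:
                best, best_pair = key, (t1, t2)
    return best_pair


# ---------------------------------------------------------------------------
# independent CSV point parser


def independent_csv_parse(path):
    """Parse x,y,z[,intensity] CSV with a header using the csv module only."""
    with open(path) as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header = [c.strip().lower() for c in rows[0]]
    xi, yi, zi = header.index("x"), header.index("y"), header.index("z")
    ii = header.index("intensity") if "intensity" in header else None
    pts, inten = [], []
    for r in rows[1:]:
        pts.append((float(r[xi]), float(r[yi]), float(r[zi])))
        if ii is not None:
            inten.append(float(r[ii]))
    return np.array(pts), (np.array(inten) if ii is not None else None)


# ---------------------------------------------------------------------------
# Delaunay circumcircle check


def circumcircle_violations(vertices: np.ndarray, triangles: np.ndarray) -> int:
    """Count triangles whose circumcircle strictly contains another vertex."""
    bad = 0
    for t in triangles:
        a, b, c = vertices[t[0]], vertices[t[1]], vertices[t[2]]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if d == 0:
            continue
        ux = (
            (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
        ) / d
        center = np.array([ux, uy])
        r = np.linalg.norm(a - center)
        dists = np.linalg.norm(vertices - center, axis=1)
        inside = dists < r * (1 - 1e-9)
        inside[t] = False
        bad += int(inside.any())
    return bad


# ---------------------------------------------------------------------------
# iterative boundary pruning, re-implemented from scratch


def reference_prune(vertices, triangles, threshold):
    """Round-based boundary pruning with explicit boundary recomputation.

    Returns the surviving triangles as a list of sorted vertex tuples.
    """
    tris = [tuple(t) for t in triangles]

    def perimeter(t):
        p = 0.0
        for i, j in ((0, 1), (1, 2), (2, 0)):
            p += math.dist(vertices[t[i]], vertices[t[j]])
        return p

    while True:
        edge_count = Counter()
        for t in tris:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                edge_count[frozenset((t[i], t[j]))] += 1
        boundary = [
            t
            for t in tris
            if any(
                edge_count[frozenset((t[i], t[j]))] == 1
                for i, j in ((0, 1), (1, 2), (2, 0))
            )
        ]
        doomed = [t for t in boundary if perimeter(t) > threshold]
        if not doomed:
            return {tuple(sorted(t)) for t in tris}
        tris = [t for t in tris if t not in doomed]


# ---------------------------------------------------------------------------
# largest empty convex polygon (exhaustive DP, O(n^3) per bottom vertex)


def _cross(o, a, b):
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _tri_area(a, b, c):
    return abs(_cross(a, b, c)) / 2.0


def _strictly_inside_triangle(p, a, b, c, eps=1e-12):
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    return (d1 > eps and d2 > eps and d3 > eps) or (d1 < -eps and d2 < -eps and d3 < -eps)


def largest_empty_convex_polygon_area(points: np.ndarray) -> float:
    """Maximum area of a convex polygon with vertices among ``points`` whose
    interior contains no point of the set.  Exhaustive dynamic program over
    the bottom-most polygon vertex and angularly sorted fans.
    """
    pts = [tuple(map(float, p)) for p in np.asarray(points)]
    n = len(pts)
    best = 0.0
    order_all = sorted(range(n), key=lambda i: (pts[i][1], pts[i][0]))
    for bi_pos, bi in enumerate(order_all):
        b = pts[bi]
        cand = order_all[bi_pos + 1 :]  # lexicographically above the bottom vertex
        S = sorted(
            cand,
            key=lambda i: (
                math.atan2(pts[i][1] - b[1], pts[i][0] - b[0]),
                (pts[i][0] - b[0]) ** 2 + (pts[i][1] - b[1]) ** 2,
            ),
        )
        m = len(S)
        if m < 2:
            continue

        def fan_empty(i, j):
            a, c = pts[S[i]], pts[S[j]]
            for q in range(n):
                if q in (bi, S[i], S[j]):
                    continue
                if _strictly_inside_triangle(pts[q], b, a, c):
                    return False
            return True

        g = [[0.0] * m for _ in range(m)]
        valid = [[False] * m for _ in range(m)]
        for j in range(m):
            for i in range(j):
                if _cross(b, pts[S[i]], pts[S[j]]) <= 0:
                    continue  # not strictly CCW around the bottom vertex
                if not fan_empty(i, j):
                    continue
                area = _tri_area(b, pts[S[i]], pts[S[j]])
                ext = 0.0
                for h in range(i):
                    if not valid[h][i]:
                        continue
                    if _cross(pts[S[h]], pts[S[i]], pts[S[j]]) >= 0:  # left turn
                        ext = max(ext, g[h][i])
                g[i][j] = area + ext
                valid[i][j] = True
                # close the polygon: turn at the last vertex must stay convex
                if _cross(pts[S[i]], pts[S[j]], b) >= 0:
                    best = max(best, g[i][j])
    return best


def largest_empty_convex_polygon_area_subsets(points: np.ndarray) -> float:
    """Tiny-n reference for the DP above: enumerate vertex subsets."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = 0.0
    for size in range(3, n + 1):
        for sub in combinations(range(n), size):
            P = pts[list(sub)]
            try:
                hull = ConvexHull(P)
            except QhullError:
                continue
            if len(hull.vertices) != size:
                continue  # some chosen point is not a polygon vertex
            poly = P[hull.vertices]
            others = [q for q in range(n) if q not in sub]
            if any(_point_in_convex(pts[q], poly) for q in others):
                continue
            best = max(best, hull.volume)  # 2D "volume" is the area
    return best


def _point_in_convex(p, poly, eps=1e-12):
    for i in range(len(poly)):
        a, b = poly[i], poly[(i + 1) % len(poly)]
        if _cross(tuple(a), tuple(b), tuple(p)) <= eps:
            return False
    return True
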