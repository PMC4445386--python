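"""Mutual k-nearest-neighbour clustering of soma clouds.

Two cells are related (``i <->k j``) iff each is among the other's k nearest
neighbours (Euclidean, self excluded).  Clusters are the connected components
of this mutual graph — equivalently, the equivalence classes of the
transitive closure of the relation — restricted to components of size >= 2;
degree-0 cells are reported separately as *isolated*.

Neighbour search is exact.  Distance ties are broken by the smaller point id
so results are deterministic and independent of point ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_io import PointCloud


@dataclass
class ClusterParams:
    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ClusterResult:
    """A partition of a cloud into mutual-kNN clusters plus isolated cells.

    ``labels[i]`` is the cluster index of point i (aligned with the input
    cloud order) or -1 for isolated points.  ``clusters`` holds member *ids*
    per cluster, sorted by size descending (ties by smallest member id).
    """

    labels: np.ndarray
    clusters: list[np.ndarray]
    isolated: np.ndarray
    k: int

    @property
    def n_points(self) -> int:
        return len(self.labels)


def _knn_indices(xyz: np.ndarray, ids: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact k nearest neighbours per point with (distance, id) tie-break."""
    n = len(xyz)
    tree = cKDTree(xyz)
    # query a few extra neighbours so boundary ties can be re-ordered by id
    m = min(n, k + 4)
    dist, idx = tree.query(xyz, k=m)
    out: list[np.ndarray] = []
    for i in range(n):
        cand = idx[i][idx[i] != i]
        d = dist[i][idx[i] != i]
        if len(cand) > k and d[k - 1] == d[k]:
            # tie straddles the cutoff: fall back to a full scan for row i
            dd = np.linalg.norm(xyz - xyz[i], axis=1)
            order = np.lexsort((ids, dd))
            order = order[order != i]
            out.append(order[:k])
        else:
            order = np.lexsort((ids[cand], d))
            out.append(cand[order][:k])
    return out


def mutual_knn_clusters(cloud: PointCloud, params: ClusterParams) -> ClusterResult:
    """Partition ``cloud`` into mutual-kNN connected components.

    Requires ``2 <= k+1 <= n``.  The result is invariant under permutations
    of the input order (up to cluster relabelling).
    """
    n = len(cloud)
    if n < 2:
        raise ValueError("need at least 2 points")
    if params.k >= n:
        raise ValueError(f"k={params.k} must be < point count {n}")

    neigh = _knn_indices(cloud.xyz, cloud.ids, params.k)
    neigh_sets = [set(a.tolist()) for a in neigh]
    rows, cols = [], []
    for i in range(n):
        for j in neigh_sets[i]:
            if i in neigh_sets[j]:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)

    degree = np.zeros(n, dtype=int)
    for i in rows:
        degree[i] += 1
    isolated_mask = degree == 0

    labels = np.full(n, -1, dtype=int)
    members: dict[int, list[int]] = {}
    for i in range(n):
        if not isolated_mask[i]:
            members.setdefault(comp[i], []).append(i)
    # order clusters by size desc, tie-break by smallest member id
    ordered = sorted(
        members.values(), key=lambda m: (-len(m), int(cloud.ids[m].min()))
    )
    clusters = []
    for ci, m in enumerate(ordered):
        m = np.asarray(m)
        labels[m] = ci
        clusters.append(np.sort(cloud.ids[m]))
    isolated = np.sort(cloud.ids[isolated_mask])
    return ClusterResult(labels=labels, clusters=clusters, isolated=isolated, k=params.k)


def cluster_summary(result: ClusterResult, small_cutoff: int = 100) -> dict:
    """Summarise a clustering: totals, largest cluster, small-cluster and
    isolated counts, and the full cluster-size histogram."""
    sizes = [len(c) for c in result.clusters]
    total = result.n_points
    largest = max(sizes) if sizes else 0
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return {
        "k": result.k,
        "total_points": total,
        "n_clusters": len(sizes),
        "largest_cluster_size": largest,
        "largest_cluster_fraction": (largest / total) if total else 0.0,
        "n_small_clusters": sum(1 for s in sizes if s < small_cutoff),
        "n_isolated": int(len(result.isolated)),
        "size_histogram": {str(k): v for k, v in sorted(hist.items())},
    }
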