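"""Soma localization in image volumes.

Stages (each usable on its own, composed by :mod:`somalayer.pipeline`):

1. optional *semantic deconvolution* — a patch-wise multilayer perceptron
   trained to render somata as bright spheres on a dark background;
2. foreground thresholding by a two-level maximum-entropy split of the
   intensity histogram;
3. seed detection: local maxima whose surrounding ball of radius ``r`` has
   mean intensity above the foreground threshold;
4. mean shift: each seed iterates to the intensity-weighted center of mass
   of foreground voxels within a spherical kernel of radius ``R``; converged
   modes closer than ``merge_radius`` are merged;
5. overlap-aware tiling for volumes too large to process at once;
6. a manifold-distance filter that drops detections lying far from the
   2D layer locally fitted through their neighbours.

Default radii ``r = R = 6`` voxels correspond to the expected soma radius at
1 µm/voxel; smaller ``r`` admits more seeds and favours recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_io import VolumeImage
from .manifold_gaps import lwr_distance

logger = logging.getLogger(__name__)


@dataclass
class LocalizationParams:
    """Knobs of the localization pipeline (lengths in voxels)."""

    r: float = 6.0
    R: float = 6.0
    t: float | str = "auto"
    max_iters: int = 100
    conv_tol: float = 0.1
    merge_radius: float | None = None  # default R/2
    substack_dims: tuple[int, int, int] = (280, 282, 246)
    substack_overlap: int = 28

    def __post_init__(self) -> None:
        if self.r <= 0 or self.R <= 0:
            raise ValueError("r and R must be positive")
        if not (0 < self.conv_tol < self.R):
            raise ValueError("conv_tol must satisfy 0 < conv_tol < R")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.merge_radius is None:
            self.merge_radius = self.R / 2.0
        if any(o <= 0 for o in self.substack_dims):
            raise ValueError("substack dims must be positive")
        if self.substack_overlap >= min(self.substack_dims):
            raise ValueError("overlap must be smaller than each substack dim")


@dataclass
class Detection:
    """A predicted soma center (sub-voxel, xyz voxel units)."""

    center: np.ndarray
    mass: float
    manifold_distance: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ValueError("detection mass must be positive")


# ---------------------------------------------------------------------------
# two-level maximum-entropy thresholding


def max_entropy_thresholds(histogram: np.ndarray) -> tuple[int, int]:
    """Two-level maximum-entropy (Kapur) thresholds of an intensity histogram.

    Returns bin indices ``(t1, t2)``, ``t1 < t2``, maximising the summed
    Shannon entropies of the classes ``[0, t1]``, ``(t1, t2]``, ``(t2, max]``.
    Partitions with all three classes populated are preferred over ones with
    an empty class (so delta-peak histograms are split between their peaks);
    ties are broken by the smallest ``(t1, t2)`` lexicographically.  The
    foreground threshold used by the pipeline is ``t1``.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or len(h) < 2:
        raise ValueError("histogram must be 1D with >= 2 bins")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram has zero total count")
    nz = np.nonzero(h)[0]
    if len(nz) == 1:
        raise ValueError("single-bin histogram: no 3-class partition possible")
    # restrict the search to the occupied range; thresholds outside it only
    # create empty classes and cannot beat an interior split
    lo, hi = int(nz[0]), int(nz[-1])
    p = h / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P = np.concatenate([[0.0], np.cumsum(p)])  # P[i] = sum p[:i]
    S = np.concatenate([[0.0], np.cumsum(plogp)])

    def class_entropy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Entropy of bins [a, b] (inclusive), vectorised; 0 for empty mass."""
        w = P[b + 1] - P[a]
        s = S[b + 1] - S[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(w > 0, np.log(w) - s / np.maximum(w, 1e-300), 0.0)
        return ent

    best_n, best = -1, -np.inf
    best_pair = (lo, lo + 1)
    last = len(h) - 1
    for t1 in range(lo, hi):
        t2s = np.arange(t1 + 1, hi + 1)
        w1 = P[t1 + 1]
        w2 = P[t2s + 1] - P[t1 + 1]
        w3 = 1.0 - P[t2s + 1]
        n_filled = (w1 > 0) + (w2 > 0).astype(int) + (w3 > 0).astype(int)
        obj = (
            class_entropy(np.array(0), np.array(t1))
            + class_entropy(np.full(len(t2s), t1 + 1), t2s)
            + class_entropy(t2s + 1, np.full(len(t2s), last))
        )
        # prefer more populated classes, then higher entropy, then smaller t2
        for n_req in (3, 2):
            mask = n_filled == n_req
            if not mask.any():
                continue
            j = int(np.argmax(np.where(mask, obj, -np.inf)))
            if (n_req, obj[j]) > (best_n, best):
                best_n, best = n_req, obj[j]
                best_pair = (t1, int(t2s[j]))
            break
    return best_pair


def auto_threshold(volume: VolumeImage) -> int:
    """Foreground threshold ``t1`` of the two-level maximum-entropy split."""
    nbins = int(np.iinfo(volume.data.dtype).max) + 1
    hist = np.bincount(volume.data.ravel(), minlength=nbins)
    t1, _ = max_entropy_thresholds(hist)
    return t1


def _resolve_threshold(volume: VolumeImage, t: float | str) -> float:
    if isinstance(t, str):
        if t != "auto":
            raise ValueError(f"threshold must be a number or 'auto', got {t!r}")
        return float(auto_threshold(volume))
    return float(t)


# ---------------------------------------------------------------------------
# seed detection


def _ball_offsets(r: float) -> np.ndarray:
    """Integer (dz, dy, dx) offsets of voxels within Euclidean distance r."""
    ri = int(np.floor(r))
    zz, yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1, -ri : ri + 1]
    mask = xx**2 + yy**2 + zz**2 <= r**2
    return np.column_stack([zz[mask], yy[mask], xx[mask]])


def detect_seeds(volume: VolumeImage, t: float | str, r: float) -> np.ndarray:
    """Seed voxels: 26-neighbourhood local maxima whose ball of radius ``r``
    has mean intensity strictly above the foreground threshold ``t``.

    Plateaus (connected equal-valued maxima) contribute a single seed, the
    lexicographically smallest ``(x, y, z)`` voxel.  The ball is truncated at
    the volume border.  Returns an ``(n, 3)`` int array of xyz voxels.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    t = _resolve_threshold(volume, t)
    data = volume.data
    # non-strict local maxima (plateau members included)
    local_max = ndimage.maximum_filter(data, size=3, mode="constant", cval=0) == data
    if not local_max.any():
        return np.empty((0, 3), dtype=int)
    # adjacent candidate maxima necessarily share their value, so connected
    # components of the candidate mask are exactly the plateaus
    labels, n_lab = ndimage.label(local_max, structure=np.ones((3, 3, 3), dtype=int))
    zz, yy, xx = np.nonzero(local_max)
    lab = labels[zz, yy, xx]
    # lexicographically smallest (x, y, z) per plateau
    order = np.lexsort((zz, yy, xx))
    zz, yy, xx, lab = zz[order], yy[order], xx[order], lab[order]
    _, first = np.unique(lab, return_index=True)
    cand = np.column_stack([zz[first], yy[first], xx[first]])

    offsets = _ball_offsets(r)
    shape = np.array(data.shape)
    seeds = []
    for czyx in cand:
        pos = czyx + offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        pos = pos[ok]
        if data[pos[:, 0], pos[:, 1], pos[:, 2]].mean() > t:
            seeds.append(czyx[::-1])  # back to (x, y, z)
    if not seeds:
        return np.empty((0, 3), dtype=int)
    out = np.array(seeds, dtype=int)
    return out[np.lexsort((out[:, 2], out[:, 1], out[:, 0]))]


# ---------------------------------------------------------------------------
# mean shift


def _merge_modes(
    centers: np.ndarray, masses: np.ndarray, radius: float
) -> list[Detection]:
    """Single-link merge of modes closer than ``radius``; each merged group
    becomes one detection at the mass-weighted mean with the summed mass."""
    if len(centers) == 0:
        return []
    tree = cKDTree(centers)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(centers)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    detections = []
    for c in np.unique(comp):
        m = comp == c
        w = masses[m]
        center = (centers[m] * w[:, None]).sum(axis=0) / w.sum()
        detections.append(Detection(center=center, mass=float(w.sum())))
    detections.sort(key=lambda d: (d.center[0], d.center[1], d.center[2]))
    return detections


def mean_shift_localize(
    volume: VolumeImage,
    seeds: np.ndarray,
    params: LocalizationParams,
    t: float | str | None = None,
) -> list[Detection]:
    """Iterate each seed to the local intensity mode and merge coincident modes.

    Only foreground voxels (intensity strictly above the threshold) carry
    mass.  Each seed moves to the mass center of the spherical kernel of
    radius ``R`` until the displacement falls below ``conv_tol`` or
    ``max_iters`` is reached; seeds whose kernel holds no foreground mass are
    dropped.  Converged modes closer than ``merge_radius`` are merged at
    their mass-weighted mean.  The detection count never exceeds the seed
    count.
    """
    t = _resolve_threshold(volume, params.t if t is None else t)
    data = volume.data.astype(float)
    shape = np.array(data.shape)
    R = params.R
    modes, masses = [], []
    for seed in np.asarray(seeds, dtype=float).reshape(-1, 3):
        pos = seed.copy()  # (x, y, z)
        mass = 0.0
        converged = False
        for _ in range(params.max_iters):
            zyx = pos[::-1]
            lo = np.maximum(np.floor(zyx - R).astype(int), 0)
            hi = np.minimum(np.ceil(zyx + R).astype(int) + 1, shape)
            zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            block = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            inside = (
                (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (zz - pos[2]) ** 2
            ) <= R**2
            fg = inside & (block > t)
            w = block[fg]
            mass = float(w.sum())
            if mass <= 0:
                logger.info("seed %s dropped: empty foreground kernel", seed)
                pos = None
                break
            new = np.array(
                [
                    (xx[fg] * w).sum() / mass,
                    (yy[fg] * w).sum() / mass,
                    (zz[fg] * w).sum() / mass,
                ]
            )
            if np.linalg.norm(new - pos) < params.conv_tol:
                pos = new
                converged = True
                break
            pos = new
        if pos is not None and (converged or params.max_iters > 0):
            modes.append(pos)
            masses.append(mass)
    return _merge_modes(np.array(modes).reshape(-1, 3), np.array(masses), params.merge_radius)


def localize_volume(
    volume: VolumeImage, params: LocalizationParams
) -> list[Detection]:
    """Threshold + seed detection + mean shift on a single (sub)volume."""
    t = _resolve_threshold(volume, params.t)
    seeds = detect_seeds(volume, t, params.r)
    return mean_shift_localize(volume, seeds, params, t=t)


# ---------------------------------------------------------------------------
# tiling


def _tile_starts(length: int, tile: int, overlap: int) -> list[int]:
    if tile >= length:
        return [0]
    step = tile - overlap
    starts = list(range(0, length - tile, step))
    starts.append(length - tile)  # final tile flush with the border
    return starts


def tile_and_merge(
    volume: VolumeImage,
    params: LocalizationParams,
    pipeline: Callable[[VolumeImage], list[Detection]] | None = None,
) -> list[Detection]:
    """Process a large volume in overlapping substacks and merge duplicates.

    Substacks of ``params.substack_dims`` step by ``dims - overlap`` along
    each axis (the last tile is flush with the border).  Each substack is
    processed independently by ``pipeline`` (default
    :func:`localize_volume`) and detections are mapped to global
    coordinates.  A detection is kept only by the tile whose *core* region
    (the tile minus half the overlap margin on interior faces) contains it,
    so somata truncated at a tile border are reported by the neighbouring
    tile that sees them whole; residual duplicate pairs across overlaps
    (within ``merge_radius``) are resolved keeping the higher-mass
    detection.  The result is independent of tile traversal order.
    """
    if pipeline is None:
        pipeline = lambda sub: localize_volume(sub, params)  # noqa: E731
    sx, sy, sz = params.substack_dims
    nx, ny, nz = volume.dims
    half = params.substack_overlap / 2.0
    all_det: list[Detection] = []
    for x0 in _tile_starts(nx, sx, params.substack_overlap):
        for y0 in _tile_starts(ny, sy, params.substack_overlap):
            for z0 in _tile_starts(nz, sz, params.substack_overlap):
                sub = VolumeImage(
                    volume.data[z0 : z0 + sz, y0 : y0 + sy, x0 : x0 + sx],
                    voxel_size_um=volume.voxel_size_um,
                )
                core_lo = np.array(
                    [
                        0.0 if x0 == 0 else half,
                        0.0 if y0 == 0 else half,
                        0.0 if z0 == 0 else half,
                    ]
                )
                core_hi = np.array(
                    [
                        sx if x0 + sx >= nx else sx - half,
                        sy if y0 + sy >= ny else sy - half,
                        sz if z0 + sz >= nz else sz - half,
                    ]
                )
                for det in pipeline(sub):
                    if np.all(det.center >= core_lo) and np.all(det.center < core_hi):
                        all_det.append(
                            Detection(
                                center=det.center + np.array([x0, y0, z0], float),
                                mass=det.mass,
                            )
                        )
    if not all_det:
        return []
    # keep the higher-mass member of any duplicate pair (deterministic order)
    order = sorted(
        range(len(all_det)),
        key=lambda i: (-all_det[i].mass, *all_det[i].center),
    )
    centers = np.array([all_det[i].center for i in order])
    kept_idx: list[int] = []
    kept_centers: list[np.ndarray] = []
    for j, c in enumerate(centers):
        if kept_centers:
            d = np.linalg.norm(np.array(kept_centers) - c, axis=1)
            if d.min() <= params.merge_radius:
                continue
        kept_idx.append(order[j])
        kept_centers.append(c)
    kept = [all_det[i] for i in kept_idx]
    kept.sort(key=lambda d: tuple(d.center))
    return kept


# ---------------------------------------------------------------------------
# manifold-distance false-positive filter


def manifold_filter(
    detections: Sequence[Detection],
    threshold: float,
    neighborhood: int = 30,
    voxel_size_um: float = 1.0,
) -> list[Detection]:
    """Drop detections lying farther than ``threshold`` µm from the local layer.

    For each detection the residual of a locally weighted quadric fit through
    its ``neighborhood`` nearest other detections estimates the distance to
    the 2D manifold formed by nearby predictions; detections whose distance
    exceeds ``threshold`` are removed, survivors keep their distance.
    """
    dets = list(detections)
    if len(dets) < neighborhood + 1:
        raise ValueError(
            f"need more than {neighborhood} detections, got {len(dets)}"
        )
    coords = np.array([d.center for d in dets]) * voxel_size_um
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=neighborhood + 1)
    survivors = []
    for i, d in enumerate(dets):
        neigh = idx[i][idx[i] != i][:neighborhood]
        dist = lwr_distance(coords[i], coords[neigh])
        if dist <= threshold:
            survivors.append(
                Detection(center=d.center, mass=d.mass, manifold_distance=float(dist))
            )
    return survivors


# ---------------------------------------------------------------------------
# semantic deconvolution


@dataclass
class DeconvModel:
    """Patch-wise MLP enhancing somata into bright spheres.

    Architecture: 2197 inputs (13x13x13 patch), sigmoid hidden layers of 500
    and 200 units, linear 2197-unit output trained against clean targets in
    [0, 1].  ``input_scale`` normalises raw gray values to [0, 1];
    ``output_scale`` maps predictions back to the volume's dtype range.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    patch_edge: int = 13
    stride: int = 4
    input_scale: float = 255.0
    output_scale: float = 255.0

    def __post_init__(self) -> None:
        n_in = self.patch_edge**3
        if self.weights[0].shape[0] != n_in or self.weights[-1].shape[1] != n_in:
            raise ValueError("input and output widths must equal patch_edge**3")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched forward pass on normalised patches, rows = flat patches."""
        a = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = 1.0 / (1.0 + np.exp(-(a @ W + b)))
        return a @ self.weights[-1] + self.biases[-1]

    def weight_hash(self) -> str:
        """Hex digest over all parameters (for determinism checks)."""
        import hashlib

        h = hashlib.sha256()
        for arr in [*self.weights, *self.biases]:
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def save_npz(self, path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            meta=np.array(
                [self.patch_edge, self.stride, self.input_scale, self.output_scale]
            ),
            **arrays,
        )

    @classmethod
    def load_npz(cls, path) -> "DeconvModel":
        data = np.load(path)
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        meta = data["meta"]
        return cls(
            weights=[data[f"W{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            patch_edge=int(meta[0]),
            stride=int(meta[1]),
            input_scale=float(meta[2]),
            output_scale=float(meta[3]),
        )


def _init_mlp(sizes: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _mlp_forward_full(weights, biases, x):
    acts = [x]
    a = x
    for W, b in zip(weights[:-1], biases[:-1]):
        a = 1.0 / (1.0 + np.exp(-(a @ W + b)))
        acts.append(a)
    out = a @ weights[-1] + biases[-1]
    acts.append(out)
    return acts


def train_semantic_deconvolution(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    epochs: int = 20,
    seed: int = 0,
    hidden: tuple[int, int] = (500, 200),
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    input_scale: float = 255.0,
    holdout_fraction: float = 0.1,
) -> tuple[DeconvModel, dict]:
    """Train the patch-enhancement MLP on (noisy, clean) patch pairs.

    Targets must lie in [0, 1]; inputs are divided by ``input_scale``.
    Training is full-batch-shuffled Adam with mean-squared-error loss and is
    deterministic given ``seed``.  Returns the model and a report holding the
    held-out MSE at initialisation and after training (a 10% split).
    """
    if len(pairs) < 100:
        raise ValueError("need at least 100 patch pairs")
    edge = 13
    X = np.stack([np.asarray(a, dtype=float) for a, _ in pairs])
    Y = np.stack([np.asarray(b, dtype=float) for _, b in pairs])
    if X.shape[1:] != (edge, edge, edge) or Y.shape[1:] != (edge, edge, edge):
        raise ValueError(f"patches must be {edge}x{edge}x{edge}, got {X.shape[1:]}")
    if Y.min() < 0 or Y.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    n = len(X)
    X = X.reshape(n, -1) / input_scale
    Y = Y.reshape(n, -1)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold, train = perm[:n_hold], perm[n_hold:]
    Xtr, Ytr, Xho, Yho = X[train], Y[train], X[hold], Y[hold]

    sizes = [edge**3, *hidden, edge**3]
    weights, biases = _init_mlp(sizes, rng)
    mse0 = float(np.mean((_mlp_forward_full(weights, biases, Xho)[-1] - Yho) ** 2))

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), batch_size):
            batch = order[start : start + batch_size]
            xb, yb = Xtr[batch], Ytr[batch]
            acts = _mlp_forward_full(weights, biases, xb)
            delta = 2.0 * (acts[-1] - yb) / (xb.shape[0] * yb.shape[1])
            step += 1
            for li in reversed(range(len(weights))):
                gW = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    a = acts[li]
                    delta = (delta @ weights[li].T) * a * (1 - a)
                mw[li] = beta1 * mw[li] + (1 - beta1) * gW
                vw[li] = beta2 * vw[li] + (1 - beta2) * gW**2
                mb[li] = beta1 * mb[li] + (1 - beta1) * gb
                vb[li] = beta2 * vb[li] + (1 - beta2) * gb**2
                mhw = mw[li] / (1 - beta1**step)
                vhw = vw[li] / (1 - beta2**step)
                mhb = mb[li] / (1 - beta1**step)
                vhb = vb[li] / (1 - beta2**step)
                weights[li] -= learning_rate * mhw / (np.sqrt(vhw) + eps)
                biases[li] -= learning_rate * mhb / (np.sqrt(vhb) + eps)

    mse1 = float(np.mean((_mlp_forward_full(weights, biases, Xho)[-1] - Yho) ** 2))
    model = DeconvModel(
        weights=weights,
        biases=biases,
        input_scale=input_scale,
        output_scale=input_scale,
    )
    return model, {"holdout_mse_init": mse0, "holdout_mse_final": mse1, "n_holdout": n_hold}


def apply_semantic_deconvolution(
    volume: VolumeImage, model: DeconvModel, batch: int = 512
) -> VolumeImage:
    """Run the patch MLP convolutionally over a volume.

    Patches of edge 13 are evaluated at the model's stride along every axis;
    overlapping predictions are averaged per voxel, scaled back to the dtype
    range and clipped.  Border voxels covered by no full patch are copied
    from the input.
    """
    e = model.patch_edge
    nx, ny, nz = volume.dims
    if min(nx, ny, nz) < e:
        raise ValueError(f"volume {volume.dims} smaller than patch edge {e}")
    data = volume.data.astype(float)
    stride = model.stride

    def starts(length: int) -> list[int]:
        s = list(range(0, length - e + 1, stride))
        if s[-1] != length - e:
            s.append(length - e)
        return s

    acc = np.zeros_like(data)
    cnt = np.zeros_like(data)
    positions = [
        (z0, y0, x0)
        for z0 in starts(data.shape[0])
        for y0 in starts(data.shape[1])
        for x0 in starts(data.shape[2])
    ]
    for i in range(0, len(positions), batch):
        chunk = positions[i : i + batch]
        patches = np.stack(
            [
                data[z0 : z0 + e, y0 : y0 + e, x0 : x0 + e].ravel()
                for (z0, y0, x0) in chunk
            ]
        )
        preds = model.forward(patches / model.input_scale)
        for (z0, y0, x0), pred in zip(chunk, preds):
            acc[z0 : z0 + e, y0 : y0 + e, x0 : x0 + e] += pred.reshape(e, e, e)
            cnt[z0 : z0 + e, y0 : y0 + e, x0 : x0 + e] += 1.0
    covered = cnt > 0
    out = data.copy()
    out[covered] = acc[covered] / cnt[covered] * model.output_scale
    info = np.iinfo(volume.data.dtype)
    out = np.clip(np.round(out), info.min, info.max).astype(volume.data.dtype)
    return VolumeImage(out, voxel_size_um=volume.voxel_size_um)
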