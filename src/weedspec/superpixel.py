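"""Superpixelwise division: spectral reduction C -> B and entropy-rate superpixels.

The superpixel stage has two effects on a cube before patch extraction:

1. ``reduce_bands`` projects every pixel's spectrum onto the top-B principal
   spectral components, shrinking the band axis from C to B while keeping the
   spatial grid — this removes spectral redundancy.
2. ``ers_segment`` partitions the image into K contiguous superpixels by
   greedily selecting edges of a pixel similarity graph so as to maximize the
   entropy rate of a random walk on the selected subgraph plus a balancing
   term that favours segments of similar size.  ``superpixel_smooth`` then
   replaces each pixel's reduced spectrum with its segment mean, injecting
   spatial context into each pixel before windows are cut.

The greedy edge selection is deterministic: lazy evaluation with a max-heap,
ties broken by edge index.  Marginal gains are submodular, so the objective is
non-decreasing along the selection sequence (cycle edges are only taken while
their gain is positive; merges always carry the balancing bonus).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ParameterError, ShapeMismatchError
from .hsi_core import HSICube

__all__ = [
    "ReducedCube",
    "SuperpixelMap",
    "reduce_bands",
    "reconstruct",
    "ers_features",
    "ers_segment",
    "superpixel_smooth",
]


@dataclass
class ReducedCube:
    """M x N x B cube after projection onto B principal spectral components."""

    values: np.ndarray
    loadings: np.ndarray  # (C, B), orthonormal columns
    mean: np.ndarray  # (C,) spectral mean removed before projection
    explained_pct: np.ndarray  # (B,) variance shares

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ShapeMismatchError("reduced cube must be 3-D")
        if self.values.shape[2] != self.loadings.shape[1]:
            raise ShapeMismatchError("band count must match loading columns")

    @property
    def B(self) -> int:
        return self.values.shape[2]


@dataclass
class SuperpixelMap:
    """M x N segment ids in [0, K); each segment connected in the build graph."""

    segment_id: np.ndarray
    K: int
    balance_weight: float

    def __post_init__(self) -> None:
        seg = np.asarray(self.segment_id)
        if seg.ndim != 2:
            raise ShapeMismatchError("segment map must be 2-D")
        present = np.unique(seg)
        if present.size != self.K or present[0] != 0 or present[-1] != self.K - 1:
            raise ParameterError("segment ids must cover [0, K) exactly")
        self.segment_id = seg


def reduce_bands(cube: HSICube, B: int) -> ReducedCube:
    """Project each pixel spectrum onto the top-B principal components."""
    m, n, c = cube.shape
    if not 1 <= B <= c:
        raise ParameterError(f"B={B} outside [1, C={c}]")
    flat = cube.values.reshape(m * n, c)
    ncomp = min(B, flat.shape[0])
    model = PCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(flat)
    loadings = model.components_.T.copy()
    if ncomp < B:  # fewer pixels than components: pad with zero variance axes
        pad = B - ncomp
        loadings = np.hstack([loadings, np.zeros((c, pad))])
        scores = np.hstack([scores, np.zeros((flat.shape[0], pad))])
        explained = np.concatenate([model.explained_variance_ratio_, np.zeros(pad)])
    else:
        explained = model.explained_variance_ratio_
    # sign convention as in spectral_analysis: largest-|.| loading element >= 0
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return ReducedCube(
        values=scores.reshape(m, n, B),
        loadings=loadings,
        mean=model.mean_,
        explained_pct=100.0 * explained,
    )


def reconstruct(rc: ReducedCube) -> np.ndarray:
    """Back-project a reduced cube to the original C-band space."""
    m, n, b = rc.values.shape
    flat = rc.values.reshape(m * n, b) @ rc.loadings.T + rc.mean
    return flat.reshape(m, n, -1)


def ers_features(cube: HSICube, n_features: int = 5) -> np.ndarray:
    """Brightness-invariant feature image for superpixel segmentation.

    Canopy pixels of one species vary strongly in overall albedo (leaf angle,
    illumination), which dominates raw principal components and would make
    superpixels track brightness rather than species.  Each spectrum is
    therefore divided by its mean before projecting onto the top principal
    components, so segment boundaries follow spectral *shape*.
    Returns an ``(M, N, n_features)`` array.
    """
    v = cube.values
    norm = v / np.maximum(v.mean(axis=2, keepdims=True), 1e-12)
    m, n, c = v.shape
    rc = reduce_bands(HSICube(values=norm, grid=cube.grid), min(n_features, c))
    return rc.values


# ---------------------------------------------------------------------------
# entropy rate superpixels
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _grid_edges(m: int, n: int, connectivity: int) -> np.ndarray:
    idx = np.arange(m * n).reshape(m, n)
    pairs = [
        np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1),
        np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1),
    ]
    if connectivity == 8:
        pairs.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
        pairs.append(np.stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()], axis=1))
    elif connectivity != 4:
        raise ParameterError("connectivity must be 4 or 8")
    return np.concatenate(pairs, axis=0)


def _plogp(p: float) -> float:
    return p * np.log(p) if p > 0 else 0.0


def ers_segment(
    feature_image: np.ndarray,
    K: int,
    balance_weight: float = 0.5,
    connectivity: int = 8,
    track_objective: bool = False,
):
    """Entropy-rate superpixel segmentation of a feature image.

    Parameters
    ----------
    feature_image
        ``(M, N)`` scalar image or ``(M, N, F)`` small feature-vector image
        (typically the first principal-component image of a reduced cube).
    K
        Number of superpixels, ``1 <= K <= M*N``.
    balance_weight
        Weight lambda of the segment-size balancing term.
    track_objective
        When true, also return the cumulative objective value after every
        accepted edge (used for monotonicity diagnostics).
    """
    feat = np.asarray(feature_image, dtype=float)
    if feat.ndim == 2:
        feat = feat[:, :, None]
    if feat.ndim != 3:
        raise ShapeMismatchError("feature image must be (M, N) or (M, N, F)")
    if balance_weight < 0:
        raise ParameterError("balance weight must be >= 0")
    m, n, _ = feat.shape
    npix = m * n
    if not 1 <= K <= npix:
        raise ParameterError(f"K={K} outside [1, {npix}]")

    edges = _grid_edges(m, n, connectivity)
    fv = feat.reshape(npix, -1)
    dist = np.linalg.norm(fv[edges[:, 0]] - fv[edges[:, 1]], axis=1)
    pos = dist[dist > 0]
    sigma = np.median(pos) if pos.size else 0.0
    if sigma <= 0:  # constant image: all edges equally similar
        weights = np.ones_like(dist)
    else:
        weights = np.exp(-(dist**2) / (2.0 * sigma**2))
    weights = np.maximum(weights, 1e-12)

    w_total = weights.sum()
    w_vertex = np.zeros(npix)
    np.add.at(w_vertex, edges[:, 0], weights)
    np.add.at(w_vertex, edges[:, 1], weights)
    mu = w_vertex / (2.0 * w_total)

    # per-vertex running state for the entropy rate:
    #   sel[i]  = selected incident weight; ent[i] = -sum p log p over selected edges
    sel = np.zeros(npix)
    ent = np.zeros(npix)

    def row_delta(i: int, w: float) -> float:
        """Change of row i's entropy when a selected edge of weight w is added."""
        wi = w_vertex[i]
        loop_old = 1.0 - sel[i] / wi
        loop_new = 1.0 - (sel[i] + w) / wi
        h_old = ent[i] - _plogp(loop_old)
        h_new = ent[i] + (-_plogp(w / wi)) - _plogp(max(loop_new, 0.0))
        return h_new - h_old

    dsu = _DSU(npix)
    inv_np = 1.0 / npix

    # the entropy term scales with the (normalized) edge weights while the
    # balancing term is O(1) per merge; normalize lambda by the ratio of the
    # initial maximal gains so balance_weight is dimensionless
    init_dh = [
        mu[i] * row_delta(i, float(weights[e])) + mu[j] * row_delta(j, float(weights[e]))
        for e, (i, j) in enumerate(edges)
    ]
    db0 = 2.0 * _plogp(inv_np) - _plogp(2.0 * inv_np) + 1.0
    lam = balance_weight * max(max(init_dh), 1e-300) / db0

    def gain(e: int) -> tuple[float, bool]:
        i, j = int(edges[e, 0]), int(edges[e, 1])
        w = float(weights[e])
        dh = mu[i] * row_delta(i, w) + mu[j] * row_delta(j, w)
        ri, rj = dsu.find(i), dsu.find(j)
        merging = ri != rj
        db = 0.0
        if merging:
            pa = dsu.size[ri] * inv_np
            pb = dsu.size[rj] * inv_np
            db = _plogp(pa) + _plogp(pb) - _plogp(pa + pb) + 1.0
        return dh + lam * db, merging

    heap: list[tuple[float, int]] = [(-g, e) for e, g in enumerate(init_dh)]
    for e in range(len(edges)):
        g, _ = gain(e)
        heap[e] = (-g, e)
    heapq.heapify(heap)

    n_components = npix
    objective = 0.0
    trace: list[float] = []
    dead = np.zeros(len(edges), dtype=bool)
    while n_components > K and heap:
        neg_g, e = heapq.heappop(heap)
        if dead[e]:
            continue
        g, merging = gain(e)
        if heap and -heap[0][0] > g + 1e-15:
            heapq.heappush(heap, (-g, e))
            continue
        if not merging:
            if g <= 0:
                dead[e] = True
                continue
        else:
            dsu.union(edges[e, 0], edges[e, 1])
            n_components -= 1
        i, j = int(edges[e, 0]), int(edges[e, 1])
        w = float(weights[e])
        for v in (i, j):
            ent[v] += -_plogp(w / w_vertex[v])
            sel[v] += w
        dead[e] = True
        objective += g
        trace.append(objective)

    if n_components != K:
        raise ParameterError("graph exhausted before reaching K segments")
    roots = np.array([dsu.find(i) for i in range(npix)])
    _, seg = np.unique(roots, return_inverse=True)
    spmap = SuperpixelMap(
        segment_id=seg.reshape(m, n), K=n_components, balance_weight=balance_weight
    )
    if track_objective:
        return spmap, trace
    return spmap


def superpixel_smooth(rc: ReducedCube, seg: SuperpixelMap) -> ReducedCube:
    """Replace every pixel's reduced spectrum with its superpixel mean.

    A projection (idempotent) that conserves each band's global mean.
    """
    m, n, b = rc.values.shape
    if seg.segment_id.shape != (m, n):
        raise ShapeMismatchError("segment map shape does not match cube")
    flat = rc.values.reshape(m * n, b)
    ids = seg.segment_id.ravel()
    counts = np.bincount(ids, minlength=seg.K).astype(float)
    sums = np.zeros((seg.K, b))
    np.add.at(sums, ids, flat)
    means = sums / counts[:, None]
    return ReducedCube(
        values=means[ids].reshape(m, n, b),
        loadings=rc.loadings,
        mean=rc.mean,
        explained_pct=rc.explained_pct,
    )
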