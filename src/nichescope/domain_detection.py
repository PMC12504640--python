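"""Neighborhood embeddings, optional Gaussian smoothing, k-means parcellation,
and the stability scan for choosing the number of domains.

Embeddings from all tissue sections are concatenated before clustering —
cross-section integration is definitional for organ-level parcellation.
Clustering is Lloyd's algorithm with k-means||-style oversampled seeding
(oversampling factor 3) and chunked assignment/update, so memory stays
O(chunk*d + k*d); chunked and full-batch assignment are exactly identical.

Stability at a given k is measured as the mean Amari-type dissimilarity
between the centroid sets of replicate clusterings started from different
seeds; the working resolution is taken where the second derivative of the
averaged (min-max normalized) inertia and instability curves changes sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .io_core import CellTable
from .model_core import CellTransformer
from .neighborhoods import NeighborhoodIndex, batch_neighborhoods

__all__ = [
    "EmbeddingMatrix",
    "DomainLabels",
    "StabilityResult",
    "compute_embeddings",
    "smooth_embeddings",
    "spherize_embeddings",
    "cluster_domains",
    "amari_dissimilarity",
    "stability_scan",
    "select_k",
]


@dataclass
class EmbeddingMatrix:
    """N x d neighborhood representations, row-aligned to the cell table."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class DomainLabels:
    labels: np.ndarray
    k: int
    inertia: float
    seed: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels outside 0..k-1")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")


def compute_embeddings(
    model: CellTransformer,
    table: CellTable,
    index: NeighborhoodIndex,
    batch_size: int = 512,
) -> EmbeddingMatrix:
    """Pooled neighborhood vector for every reference cell (deterministic)."""
    if index.n_cells != table.n_cells:
        raise ValueError("index and table describe different cell sets")
    tokens = model.encode_cell_tokens(table.log_counts, table.cell_type)
    rows = []
    for lo in range(0, table.n_cells, batch_size):
        refs = np.arange(lo, min(lo + batch_size, table.n_cells))
        batch = batch_neighborhoods(index, refs, table)
        rows.append(model.encode_and_pool(batch, tokens))
    return EmbeddingMatrix(np.vstack(rows), provenance={"smoothing_sigma": None})


def smooth_embeddings(
    emb: EmbeddingMatrix,
    table: CellTable,
    sigma: float = 12.01,
    truncation: float = 3.0,
) -> EmbeddingMatrix:
    """Gaussian kernel regression of the embedding field over the cell cloud.

    Row i becomes the kernel-weighted average (self included) of same-section
    rows within ``truncation * sigma``; sigma=0 returns the input unchanged.
    Each output coordinate is a convex combination of input coordinates.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if emb.n_cells != table.n_cells:
        raise ValueError("embedding rows misaligned with cell table")
    if sigma == 0:
        return EmbeddingMatrix(emb.values.copy(), provenance={**emb.provenance, "smoothing_sigma": 0.0})
    out = np.empty_like(emb.values)
    coords = table.coords
    for sec in np.unique(table.section_id.astype(str)):
        idx = np.flatnonzero(table.section_id.astype(str) == sec)
        tree = cKDTree(coords[idx])
        pairs = tree.query_pairs(r=truncation * sigma, output_type="ndarray")
        n = len(idx)
        w = np.exp(
            -np.sum((coords[idx[pairs[:, 0]]] - coords[idx[pairs[:, 1]]]) ** 2, axis=1)
            / (2.0 * sigma**2)
        ) if len(pairs) else np.empty(0)
        rows = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
        vals = np.concatenate([w, w, np.ones(n)])
        W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        norm = np.asarray(W.sum(axis=1)).ravel()
        out[idx] = (W @ emb.values[idx]) / norm[:, None]
    return EmbeddingMatrix(out, provenance={**emb.provenance, "smoothing_sigma": sigma})


def spherize_embeddings(emb: EmbeddingMatrix | np.ndarray, n_components: int) -> EmbeddingMatrix:
    """Project onto the leading principal components and rescale each to unit
    variance (PCA whitening).

    Small models trained for few epochs concentrate most embedding variance
    in very few directions while still encoding domain identity in weaker
    ones; Euclidean k-means on the raw matrix then quantizes the dominant
    axis and ignores the rest.  Whitening the top components (a good default
    is the number of domains k being fit) equalizes their influence.
    """
    X = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    n_components = int(min(n_components, *X.shape))
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    prov = dict(emb.provenance) if isinstance(emb, EmbeddingMatrix) else {}
    prov["spherized_components"] = n_components
    return EmbeddingMatrix(u[:, :n_components] * np.sqrt(len(X)), provenance=prov)


# -- k-means --------------------------------------------------------------

def _chunked_assign(X, centroids, chunk: int):
    """Exact nearest-centroid assignment in memory-bounded chunks."""
    n = X.shape[0]
    labels = np.empty(n, dtype=np.int64)
    dist2 = np.empty(n)
    c2 = (centroids**2).sum(axis=1)
    for lo in range(0, n, chunk):
        xb = X[lo : lo + chunk]
        d2 = (xb**2).sum(axis=1)[:, None] - 2.0 * xb @ centroids.T + c2[None, :]
        labels[lo : lo + chunk] = np.argmin(d2, axis=1)
        dist2[lo : lo + chunk] = np.maximum(d2[np.arange(len(xb)), labels[lo : lo + chunk]], 0.0)
    return labels, dist2


def _kmeans_parallel_init(X, k, rng, oversampling: float = 3.0, rounds: int = 5):
    """k-means||-style seeding: oversample candidates, then reduce to k."""
    n = X.shape[0]
    first = int(rng.integers(n))
    cand = [first]
    d2 = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(rounds):
        total = d2.sum()
        if total <= 0:
            break
        probs = np.minimum(oversampling * k * d2 / total, 1.0)
        new = np.flatnonzero(rng.random(n) < probs)
        if len(new) == 0:
            continue
        cand.extend(new.tolist())
        for c in new:
            d2 = np.minimum(d2, ((X - X[c]) ** 2).sum(axis=1))
    cand = np.unique(np.asarray(cand))
    C = X[cand]
    # weight candidates by how many points they attract, then weighted k-means++
    lab, _ = _chunked_assign(X, C, chunk=4096)
    wts = np.bincount(lab, minlength=len(cand)).astype(float)
    return _weighted_kmeanspp(C, wts, k, rng)


def _weighted_kmeanspp(C, w, k, rng):
    if len(C) <= k:
        picks = list(range(len(C)))
        # top up with duplicated farthest candidates if too few
        while len(picks) < k:
            picks.append(int(rng.integers(len(C))))
        return C[np.asarray(picks)]
    picks = [int(rng.choice(len(C), p=w / w.sum()))]
    d2 = ((C - C[picks[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        probs = w * d2
        if probs.sum() <= 0:
            picks.append(int(rng.integers(len(C))))
        else:
            picks.append(int(rng.choice(len(C), p=probs / probs.sum())))
        d2 = np.minimum(d2, ((C - C[picks[-1]]) ** 2).sum(axis=1))
    return C[np.asarray(picks)]


def _lloyd(X, k, rng, max_iter, tol=1e-6, chunk=4096, oversampling=3.0):
    centroids = _kmeans_parallel_init(X, k, rng, oversampling=oversampling)
    prev_inertia = np.inf
    labels, d2 = _chunked_assign(X, centroids, chunk)
    for _ in range(max_iter):
        inertia = float(d2.sum())
        reseeded = False
        sums = np.zeros_like(centroids)
        np.add.at(sums, labels, X)
        counts = np.bincount(labels, minlength=k).astype(float)
        empty = np.flatnonzero(counts == 0)
        for e in empty:  # re-seed empty clusters from the farthest point
            far = int(np.argmax(d2))
            centroids[e] = X[far]
            sums[e] = X[far]
            counts[e] = 1.0
            d2[far] = 0.0
            reseeded = True
        nonempty = counts > 0
        centroids[nonempty] = sums[nonempty] / counts[nonempty, None]
        labels, d2 = _chunked_assign(X, centroids, chunk)
        new_inertia = float(d2.sum())
        if not reseeded:
            assert new_inertia <= inertia + 1e-9 * max(inertia, 1.0), "inertia increased"
        if prev_inertia - new_inertia <= tol * max(prev_inertia, 1e-12) and not reseeded:
            prev_inertia = new_inertia
            break
        prev_inertia = new_inertia
    return labels, centroids, prev_inertia


def cluster_domains(
    emb: EmbeddingMatrix | np.ndarray,
    k: int,
    n_init: int = 3,
    max_iter: int = 1000,
    seed: int = 0,
    chunk: int = 4096,
    return_centroids: bool = False,
):
    """Best-of-``n_init`` k-means over the concatenated embedding matrix."""
    X = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_init):
        labels, centroids, inertia = _lloyd(X, k, rng, max_iter, chunk=chunk)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    result = DomainLabels(labels=labels, k=k, inertia=inertia, seed=seed)
    return (result, centroids) if return_centroids else result


# -- stability ------------------------------------------------------------

def amari_dissimilarity(D: np.ndarray, Dp: np.ndarray) -> float:
    """Permutation-tolerant distance between two K x d centroid sets.

    diss = (1/2K) * (2K - sum_k max_j C_kj - sum_j max_k C_kj), with C the
    K x K Pearson correlation matrix between centroids (correlated across
    the d embedding dimensions).  Zero iff the sets match up to permutation
    (and sign of correlation 1); always in [0, 2].
    """
    D, Dp = np.asarray(D, float), np.asarray(Dp, float)
    if D.shape != Dp.shape:
        raise ValueError("centroid sets must have identical shapes")
    K = D.shape[0]

    def standardize(M, tag):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = Mc.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if len(bad):
            raise ValueError(f"centroid {bad[0]} of {tag} is constant; correlation undefined")
        return Mc / sd[:, None]

    Za, Zb = standardize(D, "D"), standardize(Dp, "D'")
    C = (Za @ Zb.T) / D.shape[1]
    return float((2 * K - C.max(axis=1).sum() - C.max(axis=0).sum()) / (2 * K))


@dataclass
class StabilityResult:
    k_grid: list[int]
    mean_dissimilarity: list[float]
    mean_inertia: list[float]
    centroid_sets: dict[int, list[np.ndarray]]
    selected_k: int | None = None


def stability_scan(
    emb: EmbeddingMatrix | np.ndarray,
    k_grid,
    replicates: int = 20,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 1000,
) -> StabilityResult:
    """Replicate k-means at each k and aggregate pairwise centroid dissimilarity."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    k_grid = sorted(int(k) for k in k_grid)
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(len(k_grid), replicates))
    mean_diss, mean_inertia, centroid_sets = [], [], {}
    for row, k in enumerate(k_grid):
        sets, inertias = [], []
        for s in rep_seeds[row]:
            try:
                res, cents = cluster_domains(
                    emb, k, n_init=n_init, max_iter=max_iter, seed=int(s), return_centroids=True
                )
            except ValueError as err:
                raise ValueError(f"clustering failed at k={k}: {err}") from err
            sets.append(cents)
            inertias.append(res.inertia)
        pair_diss = [
            amari_dissimilarity(sets[i], sets[j])
            for i in range(replicates)
            for j in range(i + 1, replicates)
        ]
        mean_diss.append(float(np.mean(pair_diss)))
        mean_inertia.append(float(np.mean(inertias)))
        centroid_sets[k] = sets
    result = StabilityResult(k_grid, mean_diss, mean_inertia, centroid_sets)
    if len(k_grid) >= 4:
        result.selected_k = select_k(result, warn=False)
    return result


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    span = v.max() - v.min()
    return np.zeros_like(v) if span == 0 else (v - v.min()) / span


def select_k(result: StabilityResult, warn: bool = True) -> int | None:
    """First k where the second derivative of the averaged normalized
    inertia + instability curve changes sign (central differences)."""
    k = np.asarray(result.k_grid, float)
    if len(k) < 4:
        raise ValueError("need at least 4 grid points to locate an inflection")
    curve = 0.5 * (_minmax(result.mean_inertia) + _minmax(result.mean_dissimilarity))
    d2 = np.gradient(np.gradient(curve, k), k)
    signs = np.sign(d2)
    for i in range(1, len(signs)):
        if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]:
            return int(result.k_grid[i])
    if warn:
        warnings.warn("no second-derivative sign change on the scanned grid", stacklevel=2)
    return None
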