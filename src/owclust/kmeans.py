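"""k-means with k-means++ initialisation, batched across random starts.

The clustering stage runs inside cross-validation folds, consensus rounds and
gap-statistic reference draws, so Lloyd iterations are vectorised over all
random starts at once (centroid tensors of shape (starts, k, d)).  Convergence
is per start: every centroid must move less than ``tol`` between consecutive
iterations.  The best start by within-cluster sum of squares wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Embedding

__all__ = ["KMeansFit", "kmeans_fit", "kmeans_on_embedding", "assign_to_centroids"]


@dataclass
class KMeansFit:
    labels: np.ndarray     # (n,) 0-based cluster indices
    centroids: np.ndarray  # (k, d)
    wss: float


def _kmeanspp_init(X: np.ndarray, k: int, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for all starts at once; returns (n_starts, k, d)."""
    n, d = X.shape
    centers = np.empty((n_starts, k, d))
    first = rng.integers(n, size=n_starts)
    centers[:, 0] = X[first]
    if k == 1:
        return centers
    # D2[s, i] = squared distance of point i to its nearest chosen centre in start s
    D2 = np.sum((X[None, :, :] - centers[:, 0][:, None, :]) ** 2, axis=2)
    for c in range(1, k):
        total = D2.sum(axis=1, keepdims=True)
        # degenerate: all points coincide with chosen centres -> uniform draw
        probs = np.where(total > 0, D2 / np.where(total == 0, 1, total), 1.0 / n)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_starts)
        idx = np.minimum((cum < u[:, None]).sum(axis=1), n - 1)
        centers[:, c] = X[idx]
        newd = np.sum((X[None, :, :] - centers[:, c][:, None, :]) ** 2, axis=2)
        np.minimum(D2, newd, out=D2)
    return centers


def kmeans_fit(
    X: np.ndarray,
    k: int,
    n_starts: int = 100,
    max_iter: int = 100,
    tol: float = 1e-5,
    rng: np.random.Generator | int | None = None,
) -> KMeansFit:
    """Best-of-``n_starts`` k-means solution on raw coordinates (k >= 1)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    rng = np.random.default_rng(rng)
    C = _kmeanspp_init(X, k, n_starts, rng)  # (S, k, d)
    S = n_starts
    x_sq = np.einsum("nd,nd->n", X, X)
    labels = np.zeros((S, n), dtype=int)
    eye = np.arange(k)
    for _ in range(max_iter):
        # assignment step for every start via one GEMM
        cross = X @ C.reshape(S * k, d).T                    # (n, S*k)
        c_sq = np.einsum("skd,skd->sk", C, C)                # (S, k)
        d2 = c_sq[None, :, :] - 2.0 * cross.reshape(n, S, k)  # x_sq constant in argmin
        labels = np.argmin(d2, axis=2).T                     # (S, n)
        onehot = labels[:, :, None] == eye                   # (S, n, k)
        counts = onehot.sum(axis=1)                          # (S, k)
        sums = np.einsum("snk,nd->skd", onehot, X)
        newC = np.where(counts[:, :, None] > 0, sums / np.maximum(counts, 1)[:, :, None], C)
        # repair empty clusters: move centroid to the farthest point of that start
        empty_s, empty_c = np.nonzero(counts == 0)
        if len(empty_s):
            assigned_d2 = np.take_along_axis(
                d2.transpose(1, 0, 2), labels[:, :, None], axis=2
            )[:, :, 0] + x_sq[None, :]
            for s, c in zip(empty_s, empty_c):
                newC[s, c] = X[np.argmax(assigned_d2[s])]
        shift = np.sqrt(np.max(np.sum((newC - C) ** 2, axis=2), axis=1))
        C = newC
        if np.all(shift < tol):
            break
    # final assignment and WSS per start
    cross = X @ C.reshape(S * k, d).T
    c_sq = np.einsum("skd,skd->sk", C, C)
    d2 = x_sq[:, None, None] + c_sq[None, :, :] - 2.0 * cross.reshape(n, S, k)
    np.maximum(d2, 0.0, out=d2)
    labels = np.argmin(d2, axis=2).T
    wss = np.take_along_axis(d2.transpose(1, 0, 2), labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    best = int(np.argmin(wss))
    best_labels = labels[best]
    # relabel clusters in order of first appearance for a deterministic output
    remap = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    centroids = np.zeros((k, C.shape[2]))
    for old, new in remap.items():
        centroids[new] = C[best, old]
    # clusters that stayed empty keep their last centroid position
    unused = [c for c in range(k) if c not in remap]
    for j, old in enumerate(unused):
        centroids[len(remap) + j] = C[best, old]
    return KMeansFit(labels=out, centroids=centroids, wss=float(wss[best]))


def kmeans_on_embedding(
    emb: Embedding,
    k: int,
    n_starts: int = 100,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int | np.random.Generator | None = None,
) -> KMeansFit:
    """k-means++ on MDS coordinates; requires 2 <= k <= N-1."""
    n = emb.coordinates.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= {n - 1}, got {k}")
    return kmeans_fit(emb.coordinates, k, n_starts=n_starts, max_iter=max_iter,
                      tol=tol, rng=seed)


def assign_to_centroids(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment (squared Euclidean, ties to smaller index)."""
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)
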