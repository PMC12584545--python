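"""Weighted distances, modality integration and classical-MDS embedding."""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .datatypes import DistanceMatrix, Embedding, FeatureWeights, IntegratedDistance, ModalityMatrix

logger = logging.getLogger(__name__)

__all__ = ["weighted_distance_matrix", "integrate_distances", "embed_distance_matrix"]


def weighted_distance_matrix(X: ModalityMatrix, w: FeatureWeights) -> DistanceMatrix:
    """Pairwise weighted Euclidean distances d(a,b) = sqrt(sum_j w_j (a_j-b_j)^2).

    Equivalent to plain Euclidean distance after scaling each column by
    sqrt(w_j); weights must be non-negative.
    """
    if len(w.weight) != X.n_features:
        raise ValueError("weight vector length does not match feature count")
    if np.any(w.weight < 0):
        raise ValueError("negative feature weight")
    Y = X.values * np.sqrt(w.weight)
    sq = np.sum(Y * Y, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, sample_ids=X.sample_ids)


def integrate_distances(ds: list[DistanceMatrix]) -> IntegratedDistance:
    """Average per-modality distance matrices: I_w = sum_m (1/M) D_m."""
    if len(ds) == 0:
        raise ValueError("need at least one distance matrix")
    ids = ds[0].sample_ids
    for d in ds[1:]:
        if not np.array_equal(d.sample_ids, ids):
            raise ValueError("distance matrices have mismatched sample sets/order")
    M = len(ds)
    values = sum(d.values for d in ds) / M
    return IntegratedDistance(values=values, sample_ids=ids,
                              gammas=np.full(M, 1.0 / M))


def embed_distance_matrix(I: DistanceMatrix, d_max: int | None = None,
                          eig_tol: float = 1e-8) -> Embedding:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres -1/2 D*D, eigendecomposes, and keeps components with
    eigenvalue > ``eig_tol`` (at most ``d_max``).  Coordinates are eigenvectors
    scaled by sqrt(eigenvalue); pairwise Euclidean distances between the
    coordinates reproduce the input exactly when it is Euclidean-embeddable.
    Negative eigenvalues (non-Euclidean input) are dropped with a warning.
    """
    n = I.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to embed a distance matrix")
    D2 = I.values**2
    # double centring: B = -1/2 J D2 J with J = I - 11'/n
    row = D2.mean(axis=0)
    B = -0.5 * (D2 - row[:, None] - row[None, :] + D2.mean())
    eigval, eigvec = scipy.linalg.eigh(B)
    eigval = eigval[::-1]
    eigvec = eigvec[:, ::-1]
    neg_energy = -eigval[eigval < -eig_tol].sum()
    pos_energy = eigval[eigval > eig_tol].sum()
    if neg_energy > 0:
        # averaging per-modality Euclidean metrics is generically *slightly*
        # non-Euclidean; only a substantial negative share deserves a warning
        level = logging.WARNING if neg_energy > 0.05 * max(pos_energy, eig_tol) else logging.DEBUG
        logger.log(level,
                   "distance matrix is not Euclidean-embeddable; dropping negative "
                   "eigenvalue energy %.3g (positive energy %.3g)", neg_energy, pos_energy)
    keep = eigval > eig_tol
    if d_max is not None:
        keep &= np.arange(n) < d_max
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    return Embedding(coordinates=coords, eigenvalues=lam, sample_ids=I.sample_ids)
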