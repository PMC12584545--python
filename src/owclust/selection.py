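"""Cluster-number selection: cross-validated prediction index and gap statistic.

Two complementary criteria over a grid of candidate k:

* CPI(k): average held-out within-cluster sum of squares over repeated
  train/test splits of the outcome-weighted embedding (smaller = better
  generalisation).
* Gap(k): expected log within-cluster dispersion under a uniform reference
  null minus the observed log dispersion (larger = stronger structure).

The selected k maximises the sum of the two criteria after each is rescaled
to [0, 1] over the grid (the CPI enters negated, being an error).  Raw values
are retained so the decision can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import cox_feature_weights
from .datatypes import Embedding, ModalityMatrix, SurvivalData
from .distance import embed_distance_matrix, integrate_distances, weighted_distance_matrix
from .kmeans import assign_to_centroids, kmeans_fit

__all__ = ["CPIResult", "GapResult", "KSelectionResult",
           "cpi_score", "gap_statistic", "select_k"]


@dataclass
class CPIResult:
    k_grid: np.ndarray
    cpi_raw: np.ndarray          # mean held-out WSS per k
    per_split: np.ndarray        # (m, len(k_grid))
    m: int
    details: list = field(default_factory=list, repr=False)


@dataclass
class GapResult:
    k_grid: np.ndarray
    gap: np.ndarray
    ref_log_wss_mean: np.ndarray
    obs_log_wss: np.ndarray
    se_gap: np.ndarray
    B: int
    ref_log_wss: np.ndarray = None  # (B, len(k_grid)) for audit


@dataclass
class KSelectionResult:
    k_grid: np.ndarray
    cpi_score: np.ndarray
    gap_score: np.ndarray
    combined: np.ndarray
    k_selected: int


def _pooled_wss(X: np.ndarray) -> float:
    return float(np.sum((X - X.mean(axis=0)) ** 2))


def _log_wss(X: np.ndarray, k: int, n_starts: int, rng) -> float:
    """log of the k-means within-cluster sum of squares (k = 1 is the pooled SS)."""
    wss = _pooled_wss(X) if k == 1 else kmeans_fit(X, k, n_starts=n_starts, rng=rng).wss
    return float(np.log(wss))


def cpi_score(
    blocks: list[ModalityMatrix],
    surv: SurvivalData,
    k_grid,
    m: int = 20,
    split_fraction: float = 0.5,
    seed=None,
    n_starts: int = 100,
    return_details: bool = False,
) -> CPIResult:
    """Cross-validated prediction index over a k grid.

    Per split: feature weights are estimated on the training part, the
    weighted embedding spans all samples, k-means centroids come from the
    training rows, and held-out samples contribute their squared distance to
    the nearest centroid.  CPI(k) averages that test sum over ``m`` splits.
    """
    k_grid = np.asarray(list(k_grid), dtype=int)
    rng = np.random.default_rng(seed)
    n = surv.n_samples
    n_train = int(round(n * split_fraction))
    n_test = n - n_train
    if np.any(k_grid >= n_test):
        raise ValueError(f"largest k ({k_grid.max()}) must be below the test-set size ({n_test})")
    per_split = np.empty((m, len(k_grid)))
    details = []
    for i in range(m):
        for _attempt in range(10):
            perm = rng.permutation(n)
            train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            if surv.event[train_idx].sum() >= 2:
                break
        else:
            raise ValueError("could not draw a training split with >= 2 events")
        surv_tr = surv.take_samples(train_idx)
        weights = [cox_feature_weights(b.take_samples(train_idx), surv_tr) for b in blocks]
        ds = [weighted_distance_matrix(b, w) for b, w in zip(blocks, weights)]
        emb = embed_distance_matrix(integrate_distances(ds))
        split_detail = {"train_idx": train_idx, "test_idx": test_idx,
                        "coordinates": emb.coordinates, "centroids": {}}
        for j, k in enumerate(k_grid):
            km = kmeans_fit(emb.coordinates[train_idx], k, n_starts=n_starts, rng=rng)
            test = emb.coordinates[test_idx]
            assign = assign_to_centroids(test, km.centroids)
            per_split[i, j] = float(np.sum((test - km.centroids[assign]) ** 2))
            split_detail["centroids"][int(k)] = km.centroids
        if return_details:
            details.append(split_detail)
    return CPIResult(k_grid=k_grid, cpi_raw=per_split.mean(axis=0),
                     per_split=per_split, m=m, details=details)


def gap_statistic(
    emb: Embedding,
    k_grid,
    B: int = 50,
    seed=None,
    n_starts: int = 100,
    ref_n_starts: int = 10,
) -> GapResult:
    """Gap statistic on embedding coordinates with a uniform-box reference.

    Gap(k) = E*[log W*_k] - log W_k, where W_k is the k-means within-cluster
    sum of squares (squared Euclidean) and the expectation is a mean over
    ``B`` datasets drawn uniformly over the per-coordinate range of the
    observed coordinates.  ``se_gap`` is sd(log W*_k) * sqrt(1 + 1/B).
    """
    if B < 10:
        raise ValueError("B must be at least 10 for a stable reference null")
    k_grid = np.asarray(list(k_grid), dtype=int)
    rng = np.random.default_rng(seed)
    X = emb.coordinates
    obs = np.array([_log_wss(X, k, n_starts, rng) for k in k_grid])
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = np.empty((B, len(k_grid)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = [_log_wss(Xb, k, ref_n_starts, rng) for k in k_grid]
    ref_mean = ref.mean(axis=0)
    gap = ref_mean - obs
    se = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapResult(k_grid=k_grid, gap=gap, ref_log_wss_mean=ref_mean,
                     obs_log_wss=obs, se_gap=se, B=B, ref_log_wss=ref)


def _minmax(x: np.ndarray) -> np.ndarray:
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng_


def select_k(cpi: CPIResult, gap: GapResult) -> KSelectionResult:
    """Pick k maximising rescaled(-CPI) + rescaled(Gap); ties to smaller k."""
    if not np.array_equal(cpi.k_grid, gap.k_grid):
        raise ValueError("CPI and Gap were computed on different k grids")
    cpi_s = _minmax(-cpi.cpi_raw)
    gap_s = _minmax(gap.gap)
    combined = cpi_s + gap_s
    k_selected = int(cpi.k_grid[int(np.argmax(combined))])
    return KSelectionResult(k_grid=cpi.k_grid, cpi_score=cpi_s, gap_score=gap_s,
                            combined=combined, k_selected=k_selected)
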