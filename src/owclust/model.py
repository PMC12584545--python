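"""Outcome-weighted integrative clustering model.

The estimator couples per-feature univariate Cox weights, weighted Euclidean
distances per modality, uniform modality averaging, classical-MDS embedding
and k-means, wrapped in K-fold cross-validation with consensus voting across
rounds.  Survival information enters only through the feature weights, which
are always estimated on training folds, so held-out cluster assignments never
reuse the outcome of the samples being labelled.

Usage follows the model/results idiom::

    model = SurvClust(blocks, survival)
    res = model.fit(k=2, n_rounds=50, n_folds=3, seed=1)
    res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cox import cox_feature_weights
from .datatypes import (
    ClusteringSolution,
    Embedding,
    FeatureWeights,
    IntegratedDistance,
    ModalityMatrix,
    SurvivalData,
)
from .distance import embed_distance_matrix, integrate_distances, weighted_distance_matrix
from .kmeans import assign_to_centroids, kmeans_fit
from .preprocess import filter_degenerate_features, standardize_features

logger = logging.getLogger(__name__)

__all__ = ["SurvClust", "SurvClustResults", "fit_survclust_round", "survclust_consensus",
           "align_labels", "consensus_vote"]


def align_labels(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Permute 0-based cluster indices of ``labels`` to best match ``reference``.

    Solves the assignment problem on the confusion matrix (Hungarian
    algorithm), maximising the number of agreeing samples.
    """
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (labels, reference), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.empty(k, dtype=int)
    mapping[rows] = cols
    return mapping[labels]


def consensus_vote(round_labels: np.ndarray, k: int):
    """Majority vote over aligned rounds; ties go to the smaller label index.

    Returns 0-based consensus labels and the per-sample agreement fraction.
    """
    n_rounds, n = round_labels.shape
    counts = np.zeros((k, n), dtype=int)
    for r in range(n_rounds):
        np.add.at(counts, (round_labels[r], np.arange(n)), 1)
    consensus = counts.argmax(axis=0)  # argmax returns the first (smallest) max
    agreement = counts.max(axis=0) / n_rounds
    return consensus, agreement


class SurvClust:
    """Outcome-weighted integrative clustering of multimodal feature blocks.

    Parameters
    ----------
    blocks : list of ModalityMatrix
        One block per modality; all blocks must cover the same samples.
        Blocks are filtered for degenerate columns and z-scored unless already
        flagged standardized.
    survival : SurvivalData
        Right-censored outcome driving the feature weights (event 1 = death,
        times in months).
    """

    def __init__(self, blocks: list[ModalityMatrix], survival: SurvivalData,
                 max_zero_fraction: float = 0.95):
        if len(blocks) == 0:
            raise ValueError("need at least one feature block")
        ids = blocks[0].sample_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for b in blocks[1:]:
            if set(b.sample_ids) != set(ids):
                raise ValueError("blocks do not share the same sample set")
        if set(survival.sample_ids) != set(ids):
            raise ValueError("survival data does not cover the block samples")
        if np.any(survival.time <= 0):
            raise ValueError("zero or negative survival times are not allowed")

        # canonical sample order (sorted ids): makes every downstream step,
        # including seeded splits and k-means starts, invariant to the input
        # row order — permuting the input permutes the labels identically.
        self._order = np.argsort(ids, kind="stable")
        canon = ids[self._order]
        self.sample_ids = ids  # original input order, used for all outputs

        def reorder_block(b: ModalityMatrix) -> ModalityMatrix:
            pos = {s: i for i, s in enumerate(b.sample_ids)}
            idx = np.array([pos[s] for s in canon])
            return b.take_samples(idx)

        prepared = []
        for b in blocks:
            b = reorder_block(b)
            if not b.standardized:
                b, removed = filter_degenerate_features(b, max_zero_fraction)
                b = standardize_features(b)
            prepared.append(b)
        self.blocks = prepared
        pos = {s: i for i, s in enumerate(survival.sample_ids)}
        self.survival = survival.take_samples(np.array([pos[s] for s in canon]))
        self.n_samples = len(canon)
        self._canon_ids = canon

    # ------------------------------------------------------------------ #

    def _fold_weights(self, train_idx: np.ndarray) -> list[FeatureWeights]:
        surv_tr = self.survival.take_samples(train_idx)
        return [cox_feature_weights(b.take_samples(train_idx), surv_tr) for b in self.blocks]

    def _weighted_embedding(self, weights: list[FeatureWeights]) -> Embedding:
        ds = [weighted_distance_matrix(b, w) for b, w in zip(self.blocks, weights)]
        return embed_distance_matrix(integrate_distances(ds))

    def integrated_distance(self, weights: list[FeatureWeights] | None = None) -> IntegratedDistance:
        """I_w using the given (default: full-cohort) feature weights."""
        if weights is None:
            weights = self._fold_weights(np.arange(self.n_samples))
        ds = [weighted_distance_matrix(b, w) for b, w in zip(self.blocks, weights)]
        return integrate_distances(ds)

    def full_embedding(self) -> Embedding:
        """MDS embedding of the full-cohort weighted integrated distance."""
        return embed_distance_matrix(self.integrated_distance())

    def fit_round(self, k: int, n_folds: int = 3,
                  seed: int | np.random.Generator | None = None,
                  n_starts: int = 100, return_details: bool = False):
        """One cross-validated labelling round (canonical sample order).

        Samples are split into ``n_folds``; per fold, Cox weights come from the
        training folds only, the weighted embedding spans all samples, k-means
        runs on the training rows, and held-out samples are assigned to the
        nearest training centroid.  Fold-local cluster indices are aligned to
        the first fold (Hungarian assignment on full-sample nearest-centroid
        labelings) before the held-out assignments are stitched together.
        """
        if k < 2:
            raise ValueError("k must be at least 2")
        if k > self.n_samples - 1:
            raise ValueError("k must not exceed n_samples - 1")
        rng = np.random.default_rng(seed)
        n = self.n_samples
        folds = np.array_split(rng.permutation(n), n_folds)
        ref_assign = None
        labels = np.empty(n, dtype=int)
        details = []
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            train_idx = np.flatnonzero(mask)
            if self.survival.event[train_idx].sum() < 2:
                raise ValueError(
                    "a training fold has no (or a single) event; use fewer folds "
                    "so each training set retains events"
                )
            weights = self._fold_weights(train_idx)
            emb = self._weighted_embedding(weights)
            km = kmeans_fit(emb.coordinates[train_idx], k, n_starts=n_starts, rng=rng)
            full_assign = assign_to_centroids(emb.coordinates, km.centroids)
            if ref_assign is None:
                ref_assign = full_assign
            else:
                full_assign = align_labels(full_assign, ref_assign, k)
            labels[test_idx] = full_assign[test_idx]
            if return_details:
                details.append({"train_idx": train_idx, "test_idx": test_idx,
                                "weights": weights})
        if return_details:
            return labels, details
        return labels

    def fit(self, k: int, n_rounds: int = 50, n_folds: int = 3,
            seed: int | None = None, n_starts: int = 100) -> "SurvClustResults":
        """Consensus clustering over ``n_rounds`` cross-validation rounds."""
        children = np.random.SeedSequence(seed).spawn(n_rounds)
        rounds = np.empty((n_rounds, self.n_samples), dtype=int)
        for r in range(n_rounds):
            lab = self.fit_round(k, n_folds=n_folds,
                                 seed=np.random.default_rng(children[r]),
                                 n_starts=n_starts)
            rounds[r] = lab if r == 0 else align_labels(lab, rounds[0], k)
        consensus, agreement = consensus_vote(rounds, k)

        emb = self.full_embedding()
        centroids = np.vstack([
            emb.coordinates[consensus == c].mean(axis=0)
            if np.any(consensus == c) else np.zeros(emb.d)
            for c in range(k)
        ])
        wss = float(np.sum((emb.coordinates - centroids[consensus]) ** 2))

        inv = np.empty(self.n_samples, dtype=int)
        inv[self._order] = np.arange(self.n_samples)  # canonical -> input order
        solution = ClusteringSolution(
            k=k,
            consensus_labels=consensus[inv] + 1,
            round_labels=rounds[:, inv] + 1,
            agreement=agreement[inv],
            centroids=centroids,
            wss=wss,
            sample_ids=self.sample_ids,
        )
        return SurvClustResults(self, solution, n_rounds=n_rounds, n_folds=n_folds, seed=seed)

    # convenience delegations to the cluster-number selection module
    def cpi(self, k_grid, m: int = 20, split_fraction: float = 0.5,
            seed: int | None = None, n_starts: int = 100):
        from .selection import cpi_score
        return cpi_score(self.blocks, self.survival, k_grid, m=m,
                         split_fraction=split_fraction, seed=seed, n_starts=n_starts)

    def gap(self, k_grid, B: int = 50, seed: int | None = None, n_starts: int = 100):
        from .selection import gap_statistic
        return gap_statistic(self.full_embedding(), k_grid, B=B, seed=seed,
                             n_starts=n_starts)

    def select_k(self, k_grid=range(2, 9), m: int = 20, B: int = 50,
                 seed: int | None = None, n_starts: int = 100):
        from .selection import select_k
        ss = np.random.SeedSequence(seed).spawn(2)
        cpi = self.cpi(k_grid, m=m, seed=np.random.default_rng(ss[0]), n_starts=n_starts)
        gap = self.gap(k_grid, B=B, seed=np.random.default_rng(ss[1]), n_starts=n_starts)
        return select_k(cpi, gap)


@dataclass
class SurvClustResults:
    """Fitted consensus clustering: labels, agreement and diagnostics."""

    model: SurvClust
    solution: ClusteringSolution
    n_rounds: int
    n_folds: int
    seed: int | None = None
    _logrank: object = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.solution.k

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.solution.consensus_labels,
                         index=self.model.sample_ids, name="consensus_label")

    @property
    def agreement(self) -> pd.Series:
        return pd.Series(self.solution.agreement,
                         index=self.model.sample_ids, name="agreement")

    @property
    def wss(self) -> float:
        return self.solution.wss

    def logrank(self, cutoff_months: float = 60.0):
        """Log-rank test of survival separation between consensus subtypes."""
        from .stats import km_logrank
        surv = SurvivalData(
            self.model.survival.time, self.model.survival.event,
            self.model.survival.sample_ids,
        )
        labels = self.labels.reindex(self.model._canon_ids).to_numpy()
        _, lr = km_logrank(surv, labels, cutoff_months=cutoff_months)
        return lr

    def to_frame(self) -> pd.DataFrame:
        return self.solution.to_dataframe()

    def plot_km(self, cutoff_months: float = 60.0, ax=None):
        """Kaplan-Meier curves of the consensus subtypes (matplotlib axes)."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        from .stats import truncate_survival

        if ax is None:
            _, ax = plt.subplots()
        surv = truncate_survival(self.model.survival, cutoff_months)
        labels = self.labels.reindex(self.model._canon_ids).to_numpy()
        for c in sorted(np.unique(labels)):
            mask = labels == c
            KaplanMeierFitter(label=f"subtype {c} (n={mask.sum()})").fit(
                surv.time[mask], surv.event[mask]).plot_survival_function(ax=ax)
        lr = self.logrank(cutoff_months)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_title(f"log-rank p = {lr.p_value:.3g}")
        return ax

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        lines = [
            "Outcome-weighted integrative clustering (consensus over "
            f"{self.n_rounds} rounds, {self.n_folds}-fold CV)",
            f"  samples: {self.model.n_samples}   modalities: {len(self.model.blocks)}"
            f"   k: {self.k}",
            f"  within-cluster SS (full-cohort embedding): {self.wss:.4g}",
            f"  mean consensus agreement: {self.solution.agreement.mean():.3f}",
            "  cluster sizes: " + ", ".join(f"{c}: {n}" for c, n in sizes.items()),
        ]
        try:
            lr = self.logrank()
            lines.append(
                f"  log-rank (5-year cutoff): chi2 = {lr.statistic:.3f}, "
                f"df = {lr.df}, p = {lr.p_value:.3g}"
            )
        except ValueError:
            pass
        return "\n".join(lines)


def fit_survclust_round(blocks, surv, k, n_folds: int = 3, seed=None, **kw):
    """Functional wrapper: one CV round of labels, in the input sample order."""
    model = SurvClust(blocks, surv)
    labels = model.fit_round(k, n_folds=n_folds, seed=seed, **kw)
    inv = np.empty(model.n_samples, dtype=int)
    inv[model._order] = np.arange(model.n_samples)
    return labels[inv] + 1


def survclust_consensus(blocks, surv, k, n_rounds: int = 50, n_folds: int = 3,
                        seed=None, **kw) -> ClusteringSolution:
    """Functional wrapper returning the consensus ClusteringSolution."""
    return SurvClust(blocks, surv).fit(k, n_rounds=n_rounds, n_folds=n_folds,
                                       seed=seed, **kw).solution
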