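"""Differential-feature screening and subtype enrichment of flagged features.

Differential screening is a per-feature Kruskal-Wallis test across subtypes
with Benjamini-Hochberg adjustment within each modality.  Enrichment flags a
feature over-/under-expressed in a sample when its cohort z-score reaches
+0.6 / -0.6, then tests each (subtype, feature, direction) cell with an
upper-tail hypergeometric test; a feature is *representative* of a subtype
when the BH-adjusted p is below 0.05, at least 2/3 of the subtype's samples
are flagged and fewer than 1/3 are flagged in every other subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ModalityMatrix
from .stats import kruskal_wallis

__all__ = ["DifferentialFeatureResult", "EnrichmentFlags",
           "differential_features", "flag_expression", "hypergeometric_enrichment",
           "Z_THRESHOLD"]

#: z-score magnitude at which a feature counts as over-/under-expressed
#: in a sample (inclusive at equality).
Z_THRESHOLD = 0.6


@dataclass
class DifferentialFeatureResult:
    """Per-feature H statistics with BH-adjusted p-values and selection flags."""

    table: pd.DataFrame  # columns: modality, feature, H, p, p_adj, selected
    alpha: float = 0.05

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def selected_features(self, modality=None) -> list:
        t = self.selected
        if modality is not None:
            t = t[t["modality"] == modality]
        return t["feature"].tolist()


@dataclass
class EnrichmentFlags:
    """Per sample x feature direction flags: +1 over, -1 under, 0 none."""

    flags: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    threshold: float = Z_THRESHOLD

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, index=self.sample_ids, columns=self.feature_ids)


def differential_features(blocks: list[ModalityMatrix], labels,
                          alpha: float = 0.05) -> DifferentialFeatureResult:
    """Kruskal-Wallis screen of every feature across subtype labels.

    BH adjustment is applied within each modality; features with adjusted
    p < ``alpha`` are selected.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 subtypes")
    rows = []
    for m_i, block in enumerate(blocks):
        if len(labels) != block.n_samples:
            raise ValueError("label vector does not align with the feature block rows")
        stats_, ps = [], []
        for j in range(block.n_features):
            r = kruskal_wallis(block.values[:, j], labels)
            stats_.append(r.statistic)
            ps.append(r.p_value)
        p_adj = multipletests(ps, method="fdr_bh")[1]
        for j in range(block.n_features):
            rows.append({"modality": m_i, "feature": block.feature_ids[j],
                         "H": stats_[j], "p": ps[j], "p_adj": p_adj[j],
                         "selected": p_adj[j] < alpha})
    return DifferentialFeatureResult(table=pd.DataFrame(rows), alpha=alpha)


def flag_expression(block: ModalityMatrix, threshold: float = Z_THRESHOLD) -> EnrichmentFlags:
    """Threshold cohort z-scores into over (+1) / under (-1) / none (0) flags."""
    if not block.standardized:
        raise ValueError("block must be standardized before flagging")
    flags = np.zeros(block.values.shape, dtype=int)
    flags[block.values >= threshold] = 1
    flags[block.values <= -threshold] = -1
    return EnrichmentFlags(flags=flags, sample_ids=block.sample_ids,
                           feature_ids=block.feature_ids, threshold=threshold)


def hypergeometric_enrichment(flags: EnrichmentFlags, labels,
                              alpha: float = 0.05,
                              within_min: float = 2.0 / 3.0,
                              other_max: float = 1.0 / 3.0) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of flags per subtype and direction.

    For subtype s, feature f and direction: population N = all samples, K =
    samples flagged for f in that direction, n = |s|, k = flagged within s;
    p = P(X >= k).  BH adjustment runs across features within each
    subtype x direction family.  The representative flag applies the
    2/3-within / <1/3-elsewhere rule on q < ``alpha``.
    """
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 subtypes")
    for g in levels:
        if not np.any(labels == g):
            raise ValueError(f"subtype {g!r} is empty")
    N = len(labels)
    out = []
    for direction, sign in (("over", 1), ("under", -1)):
        hit = flags.flags == sign                      # (N, p) boolean
        K = hit.sum(axis=0)
        frac_by_level = {g: hit[labels == g].mean(axis=0) for g in levels}
        for g in levels:
            n_g = int(np.sum(labels == g))
            k_g = hit[labels == g].sum(axis=0)
            p = scipy.stats.hypergeom.sf(k_g - 1, N, K, n_g)
            q = multipletests(p, method="fdr_bh")[1]
            within = k_g / n_g
            other = np.max([frac_by_level[h] for h in levels if h != g], axis=0)
            rep = (q < alpha) & (within >= within_min) & (other < other_max)
            for j, f in enumerate(flags.feature_ids):
                out.append({"subtype": g, "feature": f, "direction": direction,
                            "p": float(p[j]), "q": float(q[j]),
                            "within_fraction": float(within[j]),
                            "max_other_fraction": float(other[j]),
                            "representative": bool(rep[j])})
    return pd.DataFrame(out)
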