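"""Per-sample pathway activity scores via a multivariate linear model.

Expression preprocessing averages duplicate genes and samples, removes genes
and samples with more than 30 % zeros and applies log2(x+1).  Activity
scoring regresses each sample's gene vector on the pathway-gene weight
columns (ordinary least squares with intercept); the slope t-values are the
activity scores — positive means activation.  Group contrasts compare
per-sample scores between two subtypes with a Welch t-test and BH adjustment
across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ExpressionMatrix", "PathwayWeightMatrix", "ActivityScores",
           "preprocess_expression", "mlm_activity", "contrast_activity",
           "load_pathway_weights"]


@dataclass
class ExpressionMatrix:
    """genes x samples log2(x+1) expression with the preprocessing applied."""

    values: pd.DataFrame
    log_transformed: bool = True

    @property
    def genes(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns


@dataclass
class PathwayWeightMatrix:
    """genes x pathways weights; at most ``top_n`` retained genes per pathway."""

    weights: pd.DataFrame                   # genes x pathways, 0 where not retained
    retained: dict                          # pathway -> list of retained genes

    @property
    def pathways(self):
        return self.weights.columns


def load_pathway_weights(table: pd.DataFrame, top_n: int = 100) -> PathwayWeightMatrix:
    """Build the weight matrix from a long table (gene, pathway, weight, p_value).

    Per pathway, the ``top_n`` most significant genes (smallest p) are
    retained; others get weight zero.
    """
    required = {"gene", "pathway", "weight"}
    if not required.issubset(table.columns):
        raise ValueError(f"weights table needs columns {sorted(required)}")
    tab = table.copy()
    if "p_value" in tab.columns:
        tab = tab.sort_values("p_value", kind="stable")
    retained_rows = tab.groupby("pathway", sort=False).head(top_n)
    genes = pd.Index(sorted(table["gene"].unique()))
    pathways = pd.Index(sorted(table["pathway"].unique()))
    W = pd.DataFrame(0.0, index=genes, columns=pathways)
    for _, row in retained_rows.iterrows():
        W.loc[row["gene"], row["pathway"]] = row["weight"]
    retained = {p: g["gene"].tolist() for p, g in retained_rows.groupby("pathway")}
    return PathwayWeightMatrix(weights=W, retained=retained)


def preprocess_expression(raw, max_zero_fraction: float = 0.30) -> ExpressionMatrix:
    """Average duplicates, drop >30 %-zero genes/samples, apply log2(x+1).

    Idempotent: passing an already-processed :class:`ExpressionMatrix`
    returns it unchanged.
    """
    if isinstance(raw, ExpressionMatrix):
        return raw
    df = pd.DataFrame(raw).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    df = df.groupby(level=0).mean()          # duplicate genes
    df = df.T.groupby(level=0).mean().T      # duplicate samples
    gene_zero = (df == 0).mean(axis=1)
    df = df.loc[gene_zero <= max_zero_fraction]
    sample_zero = (df == 0).mean(axis=0)
    df = df.loc[:, sample_zero <= max_zero_fraction]
    if df.empty:
        raise ValueError("no genes/samples survive the zero-expression filter")
    return ExpressionMatrix(values=np.log2(df + 1.0), log_transformed=True)


@dataclass
class ActivityScores:
    """samples x pathways slope t-values (positive = activation)."""

    t_values: pd.DataFrame
    coefficients: pd.DataFrame

    @property
    def pathways(self):
        return self.t_values.columns


def mlm_activity(expr: ExpressionMatrix, weights: PathwayWeightMatrix) -> ActivityScores:
    """OLS of each sample's gene values on the pathway weight columns.

    The design is the weight matrix restricted to the union of retained
    genes, plus an intercept; per pathway t = coefficient / SE.  All samples
    share the design, so the normal equations are solved once.
    """
    W = weights.weights
    if W.shape[1] < 2:
        raise ValueError("need at least 2 pathways")
    # the regression runs on the union of retained genes: rows with an
    # all-zero weight vector carry no pathway information and are dropped
    nonzero = W.index[(W != 0).any(axis=1)]
    genes = expr.genes.intersection(nonzero)
    if len(genes) == 0:
        raise ValueError("no overlap between expression genes and weight genes")
    Y = expr.values.loc[genes].to_numpy()           # (g, s)
    Wm = W.loc[genes].to_numpy()                    # (g, k)
    g, k = Wm.shape
    design = np.column_stack([np.ones(g), Wm])
    if np.linalg.matrix_rank(design) < k + 1:
        corr = pd.DataFrame(Wm, columns=W.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            "rank-deficient weight matrix; collinear pathways include "
            f"{corr.index[i]!r} and {corr.columns[j]!r}"
        )
    df_resid = g - (k + 1)
    if df_resid < 1:
        raise ValueError("residual degrees of freedom < 1")
    XtX_inv = np.linalg.inv(design.T @ design)
    B = XtX_inv @ design.T @ Y                      # (k+1, s)
    resid = Y - design @ B
    sigma2 = np.sum(resid**2, axis=0) / df_resid    # (s,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    cols = W.columns
    t_df = pd.DataFrame(t[1:].T, index=expr.samples, columns=cols)
    b_df = pd.DataFrame(B[1:].T, index=expr.samples, columns=cols)
    return ActivityScores(t_values=t_df, coefficients=b_df)


def contrast_activity(scores: ActivityScores, labels, reference_subtype) -> pd.DataFrame:
    """Welch t contrast of per-sample activity between two subtypes.

    Positive t means the pathway is more active in the non-reference subtype;
    BH adjustment runs across pathways.  Returns a table with columns t, p,
    p_adj indexed by pathway.
    """
    labels = pd.Series(np.asarray(labels), index=scores.t_values.index)
    levels = sorted(labels.unique().tolist())
    if len(levels) != 2:
        raise ValueError("contrast requires exactly two subtypes")
    if reference_subtype not in levels:
        raise ValueError(f"reference subtype {reference_subtype!r} not among {levels}")
    other = [g for g in levels if g != reference_subtype][0]
    a = scores.t_values[labels == other]
    b = scores.t_values[labels == reference_subtype]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each subtype needs at least 2 samples")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"t": t, "p": p, "p_adj": p_adj}, index=scores.pathways)
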