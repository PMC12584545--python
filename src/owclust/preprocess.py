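"""Feature-block preprocessing: degenerate-column filtering and z-scoring."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .datatypes import ModalityMatrix

logger = logging.getLogger(__name__)

__all__ = ["filter_degenerate_features", "standardize_features"]


def filter_degenerate_features(X: ModalityMatrix, max_zero_fraction: float = 0.95):
    """Drop all-zero, zero-variance and mostly-zero feature columns.

    A column is removed when it is constant (zero variance, which covers the
    all-zero case) or when its fraction of exact zeros exceeds
    ``max_zero_fraction``.  Returns the filtered block and the list of removed
    feature names.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    sd = X.values.std(axis=0, ddof=1) if X.n_samples > 1 else np.zeros(X.n_features)
    zero_frac = (X.values == 0).mean(axis=0)
    bad = (sd == 0) | (zero_frac > max_zero_fraction)
    removed = list(X.feature_ids[bad])
    if bad.all():
        raise ValueError("all feature columns are degenerate; nothing left to analyse")
    if removed:
        logger.info("removed %d degenerate features: %s", len(removed), removed)
        X = replace(X, values=X.values[:, ~bad], feature_ids=X.feature_ids[~bad])
    return X, removed


def standardize_features(X: ModalityMatrix) -> ModalityMatrix:
    """Column-wise z-scores using the cohort mean and sample SD (ddof=1).

    Zero-variance columns must be removed first (``filter_degenerate_features``);
    their presence raises an error naming the offending column.
    """
    sd = X.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        name = X.feature_ids[np.argmax(sd == 0)]
        raise ValueError(f"zero-variance column {name!r}; run filter_degenerate_features first")
    values = (X.values - X.values.mean(axis=0)) / sd
    return replace(X, values=values, standardized=True)
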