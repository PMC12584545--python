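"""Univariate Cox proportional-hazards feature weights.

Each feature column x_j is fitted alone in the model
``h(t | x_j) = h0(t) * exp(beta_j x_j)`` by maximising the partial likelihood;
the feature weight is ``w_j = |beta_j|`` (the absolute log hazard ratio).
Tens of thousands of single-covariate fits are needed per cross-validated
consensus run, so the Newton solver is vectorised across features: all
features share the same risk-set ordering, and the score/information terms
reduce to cumulative sums over samples sorted by decreasing time (Breslow
handling of ties; synthetic and radiomic continuous times are tie-free in
practice).
"""

from __future__ import annotations

import numpy as np

from .datatypes import FeatureWeights, ModalityMatrix, SurvivalData

__all__ = ["cox_feature_weights", "univariate_cox_beta"]

#: |beta| larger than this is treated as (near-)separation; capped before use.
BETA_CAP = 10.0


def univariate_cox_beta(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
    beta_cap: float = BETA_CAP,
):
    """Vectorised single-covariate Cox partial-likelihood maximisation.

    Parameters
    ----------
    X : (n, p) covariate matrix; each column fitted independently.
    time, event : survival outcome shared by all columns.

    Returns
    -------
    beta : (p,) estimates (capped at ``beta_cap`` in absolute value)
    converged : (p,) bool; False for degenerate columns or failed fits.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("no events: univariate Cox weights are undefined")

    # sort by decreasing time so that risk set of sample i is the prefix 0..i
    order = np.argsort(-time, kind="stable")
    t_s = time[order]
    e_s = event[order].astype(bool)
    X_s = X[order]

    # Breslow ties: risk-set sums evaluated at the last index of each tie group
    # (all samples with time >= t_i).  last_in_group[i] = last index j with t_j == t_i.
    last_in_group = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        last_in_group[i : j + 1] = j
        i = j + 1

    sd = X_s.std(axis=0)
    degenerate = sd == 0
    beta = np.zeros(p)
    active = ~degenerate
    converged = np.zeros(p, dtype=bool)

    ev_idx = np.flatnonzero(e_s)
    grp = last_in_group[ev_idx]
    x_events = X_s[ev_idx]

    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        Xa = X_s[:, active]
        r = np.exp(Xa * b)                       # (n, p_active)
        S0 = np.cumsum(r, axis=0)[grp]           # risk-set sums at event times
        S1 = np.cumsum(r * Xa, axis=0)[grp]
        S2 = np.cumsum(r * Xa * Xa, axis=0)[grp]
        mean = S1 / S0
        U = (x_events[:, active] - mean).sum(axis=0)          # score
        info = (S2 / S0 - mean**2).sum(axis=0)                # observed information
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, U / info, 0.0)
        step = np.clip(step, -1.0, 1.0)          # guard huge steps far from optimum
        beta[active] = b + step
        done = np.abs(step) < tol
        newly = np.flatnonzero(active)[done]
        converged[newly] = True
        act = active.copy()
        act[newly] = False
        # stop iterating columns that ran away (separation / monotone likelihood)
        runaway = np.abs(beta) > beta_cap
        act[runaway] = False
        active = act

    bad = ~np.isfinite(beta)
    beta[bad] = 0.0
    converged[bad] = False
    converged[degenerate] = False
    beta = np.clip(beta, -beta_cap, beta_cap)
    return beta, converged


def cox_feature_weights(X: ModalityMatrix, surv: SurvivalData) -> FeatureWeights:
    """Per-feature weights w_j = |beta_j| from univariate Cox fits.

    Non-convergent or degenerate fits get weight 0; converged |beta| is capped
    at :data:`BETA_CAP` so no single feature can dominate the metric.
    """
    if surv.n_events < 2:
        raise ValueError("at least 2 events are required to estimate feature weights")
    if not np.array_equal(X.sample_ids, surv.sample_ids):
        raise ValueError("feature block and survival data sample order differ")
    beta, converged = univariate_cox_beta(X.values, surv.time, surv.event)
    weight = np.where(converged, np.abs(beta), 0.0)
    return FeatureWeights(beta=beta, weight=weight, converged=converged,
                          feature_ids=X.feature_ids)
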