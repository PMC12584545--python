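"""Subtype evaluation statistics.

Contingency-table chi-square (Yates-corrected for 2x2), tie-corrected
Kruskal-Wallis, Kaplan-Meier / log-rank with an administrative five-year
cutoff, and the multivariable Cox model with Wald tests, Schoenfeld
proportional-hazards diagnostics and events-per-variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .datatypes import SurvivalData

__all__ = [
    "ChiSquareResult", "KruskalResult", "KMEstimate", "LogRankResult", "CoxModelResult",
    "chi_square_test", "kruskal_wallis", "km_logrank", "fit_cox_multivariable",
    "truncate_survival",
]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool
    expected: np.ndarray


@dataclass
class KruskalResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class KMEstimate:
    """Product-limit curves per group: times, survival probabilities, at-risk."""

    groups: list
    times: dict
    survival: dict
    at_risk: dict


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxModelResult:
    """Multivariable Cox fit: per-covariate table plus model diagnostics.

    ``table`` columns: B (log HR), SE, Wald ((B/SE)^2), p, HR, CI95_low,
    CI95_high, schoenfeld_p.  ``epv`` = events / number of covariates;
    ``schoenfeld_global_p`` is an approximate global proportional-hazards
    test (sum of per-covariate chi-squares, df = number of covariates).
    """

    table: pd.DataFrame
    epv: float
    n_events: int
    schoenfeld_global_p: float
    log_likelihood: float

    def summary(self) -> str:
        lines = [self.table.round(4).to_string(),
                 f"EPV = {self.epv:.4g} ({self.n_events} events / {len(self.table)} covariates)",
                 f"Schoenfeld global p = {self.schoenfeld_global_p:.3g}"]
        return "\n".join(lines)


def chi_square_test(table, continuity: bool | str = "auto") -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    With ``continuity='auto'`` the Yates correction — replacing each
    ``(O-E)^2`` by ``max(|O-E| - 0.5, 0)^2`` — is applied exactly when the
    table is 2x2.  All expected counts must be positive (no zero marginals).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.size == 0:
        raise ValueError("table must be a 2-D count matrix")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("table must hold non-negative integer counts")
    if counts.sum() == 0:
        raise ValueError("empty table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total; drop the empty category first")
    expected = np.outer(row, col) / counts.sum()
    r, c = counts.shape
    df = (r - 1) * (c - 1)
    apply_corr = (continuity is True) or (continuity == "auto" and counts.shape == (2, 2))
    dev = np.abs(counts - expected)
    if apply_corr:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(scipy.stats.chi2.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, p_value=p,
                           correction_applied=bool(apply_corr), expected=expected)


def kruskal_wallis(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H test; df = number of groups - 1."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        # all values identical: the tie correction degenerates (0/0); H is 0
        return KruskalResult(statistic=0.0, df=len(levels) - 1, p_value=1.0)
    stat, p = scipy.stats.kruskal(*samples)
    return KruskalResult(statistic=float(stat), df=len(levels) - 1, p_value=float(p))


def truncate_survival(surv: SurvivalData, cutoff_months: float) -> SurvivalData:
    """Administrative censoring: times capped at the cutoff, later events recoded."""
    time = np.minimum(surv.time, cutoff_months)
    event = np.where(surv.time > cutoff_months, 0, surv.event)
    return SurvivalData(time, event, surv.sample_ids)


def km_logrank(surv: SurvivalData, groups, cutoff_months: float | None = 60.0):
    """Kaplan-Meier curves and log-rank test with a five-year cutoff by default.

    Events after the cutoff are recoded as censored at the cutoff before
    product-limit estimation and the standard log-rank test.
    """
    groups = np.asarray(groups)
    if len(groups) != surv.n_samples:
        raise ValueError("group labels must match the survival samples")
    if cutoff_months is not None:
        surv = truncate_survival(surv, cutoff_months)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    if surv.n_events == 0:
        raise ValueError("no events within the cutoff; log-rank test undefined")
    times, probs, at_risk = {}, {}, {}
    for g in levels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        times[g] = kmf.survival_function_.index.to_numpy()
        probs[g] = kmf.survival_function_.iloc[:, 0].to_numpy()
        at_risk[g] = kmf.event_table["at_risk"].to_numpy()
    res = multivariate_logrank_test(surv.time, groups, surv.event)
    km = KMEstimate(groups=levels, times=times, survival=probs, at_risk=at_risk)
    lr = LogRankResult(statistic=float(res.test_statistic),
                       df=len(levels) - 1, p_value=float(res.p_value))
    return km, lr


def fit_cox_multivariable(surv: SurvivalData, covariates: pd.DataFrame,
                          schoenfeld_transform: str = "km") -> CoxModelResult:
    """Multivariable Cox PH fit (Efron ties) with Wald tests and diagnostics.

    ``covariates`` is a numeric design table indexed like the survival data;
    HR = exp(B) and the 95 % CI is exp(B +/- 1.96 SE).  The Schoenfeld test
    correlates scaled residuals with (by default KM-) transformed event times
    per covariate; the global p combines the per-covariate chi-squares.
    """
    cov = covariates.astype(float)
    if cov.shape[0] != surv.n_samples:
        raise ValueError("covariate rows must match the survival samples")
    n_cov = cov.shape[1]
    if surv.n_events < n_cov:
        raise ValueError("fewer events than covariates; the fit is unstable")
    const = [c for c in cov.columns if cov[c].nunique() == 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    df = cov.copy()
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    B = cph.params_
    SE = cph.standard_errors_
    if np.any(SE > 100):
        raise ValueError("separation detected: a coefficient standard error diverged")
    wald = (B / SE) ** 2
    p = pd.Series(scipy.stats.chi2.sf(wald, 1), index=B.index)
    ph = proportional_hazard_test(cph, df, time_transform=schoenfeld_transform)
    sch_p = ph.summary["p"]
    sch_p.index = sch_p.index.get_level_values(0)
    sch_stat = ph.summary["test_statistic"]
    sch_stat.index = sch_p.index
    table = pd.DataFrame({
        "B": B, "SE": SE, "Wald": wald, "p": p,
        "HR": np.exp(B),
        "CI95_low": np.exp(B - 1.96 * SE),
        "CI95_high": np.exp(B + 1.96 * SE),
        "schoenfeld_p": sch_p.reindex(B.index),
    })
    global_stat = float(sch_stat.sum())
    global_p = float(scipy.stats.chi2.sf(global_stat, n_cov))
    return CoxModelResult(table=table, epv=surv.n_events / n_cov,
                          n_events=surv.n_events, schoenfeld_global_p=global_p,
                          log_likelihood=float(cph.log_likelihood_))
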