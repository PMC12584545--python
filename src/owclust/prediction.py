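"""Stability feature selection and the repeated-split biomarker harness.

Targets a binary molecular label (e.g. combined MGMT-promoter-methylated &
IDH-mutant vs others).  Feature selection repeats stratified 80/20 splits,
fits an L1-penalised logistic regression on the training part with the
penalty chosen by 10-fold cross-validated binomial deviance over a log-spaced
grid, and keeps features whose selection frequency reaches 10 %.  The
evaluation harness refits a panel of classifiers over many stratified splits
and reports eight threshold/rank metrics per split, model means, and a
one-way ANOVA with Dunnett many-to-one comparisons of per-split AUCs against
the best-mean model.  Extra classifiers (anything with fit/predict_proba or a
decision function) can be plugged into the model panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datatypes import SurvivalData

logger = logging.getLogger(__name__)

__all__ = ["StabilitySelectionResult", "MetricsTable", "ModelComparison",
           "compute_metrics", "stability_select", "default_models",
           "train_and_evaluate", "compare_models_dunnett", "km_check_of_predictions"]

METRIC_NAMES = ["AUC", "Se", "Sp", "ACC", "Youden", "F_measure", "MCC", "G_means"]


@dataclass
class StabilitySelectionResult:
    frequency: pd.Series          # per-feature selection frequency over splits
    selected: list                # features with frequency >= threshold
    threshold: float
    lambdas: np.ndarray           # chosen lambda per split
    n_splits: int


@dataclass
class MetricsTable:
    per_split: pd.DataFrame       # columns: split, model, the eight metrics
    summary: pd.DataFrame         # mean per model (degenerate splits excluded)
    n_excluded: dict


@dataclass
class ModelComparison:
    reference: str
    anova_F: float
    anova_p: float
    comparisons: pd.DataFrame     # model, mean_auc, diff_vs_reference, statistic, p_adj


def compute_metrics(y_true, y_score, threshold: float = 0.5) -> dict:
    """Eight binary-classification metrics from scores and a 0.5 operating point.

    AUC uses the rank (Mann-Whitney) statistic with mid-ranks for ties; the
    confusion-matrix metrics threshold the score at ``threshold``.  Undefined
    ratios (empty denominators) are reported as 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute metrics")
    y_pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * se / (prec + se) if prec + se else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return {
        "AUC": float(roc_auc_score(y_true, y_score)),
        "Se": se, "Sp": sp, "ACC": acc,
        "Youden": se + sp - 1.0,
        "F_measure": f,
        "MCC": float(mcc),
        "G_means": float(np.sqrt(se * sp)),
    }


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                 ratio: float = 1e-4) -> np.ndarray:
    """glmnet-style grid: log-spaced from the smallest all-zero lambda down."""
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _l1_logistic(C: float) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C,
                              max_iter=200, tol=1e-4)


def _deviance(clf, X_val, y_val) -> float:
    p = np.clip(clf.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
    return -2.0 * float(np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))


def _cv_lambda(X_tr, y_tr, lambdas, cv_folds: int, random_state: int,
               patience: int = 10) -> float:
    """Pick the penalty minimising cv-fold mean validation deviance.

    The path is walked from the strongest penalty downwards and abandoned
    once the cross-validated deviance has not improved for ``patience``
    consecutive grid points (the deviance path is U-shaped; the cheap
    strongly-penalised end is always explored, the expensive weak end only
    while it keeps helping).
    """
    kf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    folds = list(kf.split(X_tr, y_tr))
    best_dev, best_lam, since = np.inf, lambdas[0], 0
    for lam in lambdas:
        dev = 0.0
        for tr_idx, val_idx in folds:
            clf = _l1_logistic(1.0 / (len(tr_idx) * lam))
            clf.fit(X_tr[tr_idx], y_tr[tr_idx])
            dev += _deviance(clf, X_tr[val_idx], y_tr[val_idx])
        dev /= len(folds)
        if dev < best_dev - 1e-12:
            best_dev, best_lam, since = dev, lam, 0
        else:
            since += 1
            if since >= patience:
                break
    return float(best_lam)


def stability_select(
    features,
    labels,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    cv_folds: int = 10,
    freq_threshold: float = 0.10,
    seed: int = 1,
    n_lambda: int = 100,
) -> StabilitySelectionResult:
    """Repeated-split L1-logistic stability selection.

    Per split: a stratified ``train_fraction`` partition; 10-fold CV deviance
    on the training part picks the penalty from a log-spaced grid; features
    with non-zero coefficient at that penalty are recorded.  Split seeds run
    ``seed .. seed + n_splits - 1``; the final set keeps features selected in
    at least ``freq_threshold`` of the splits.
    """
    X, feature_ids = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < 20:
        raise ValueError("need at least 20 samples per class for stability selection")
    counts_sel = np.zeros(X.shape[1])
    lambdas = np.empty(n_splits)
    for s in range(n_splits):
        for attempt in range(10):
            X_tr, _, y_tr, _ = train_test_split(
                X, y, train_size=train_fraction, stratify=y, random_state=seed + s + attempt * 7919
            )
            if len(np.unique(y_tr)) == 2:
                break
            logger.warning("resampling split %d: a class was absent from training", s)
        else:
            raise ValueError("could not draw a training split containing both classes")
        grid = _lambda_grid(X_tr, y_tr, n_lambda=n_lambda)
        lam = _cv_lambda(X_tr, y_tr, grid, cv_folds, random_state=seed + s)
        lambdas[s] = lam
        clf = _l1_logistic(1.0 / (len(y_tr) * lam))
        clf.fit(X_tr, y_tr)
        counts_sel += (np.abs(clf.coef_[0]) > 0).astype(float)
    freq = pd.Series(counts_sel / n_splits, index=feature_ids, name="frequency")
    selected = freq.index[freq >= freq_threshold].tolist()
    return StabilitySelectionResult(frequency=freq, selected=selected,
                                    threshold=freq_threshold, lambdas=lambdas,
                                    n_splits=n_splits)


def default_models() -> dict:
    """The four standard classifiers of the prediction harness."""
    return {
        "LR": LogisticRegression(max_iter=1000),
        "RF": RandomForestClassifier(n_estimators=100),
        "SVM": SVC(kernel="rbf"),  # scored via its decision function (logistic link)
        "kNN": KNeighborsClassifier(n_neighbors=5),
    }


def _scores(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    # decision-function models: rank-preserving logistic link onto (0, 1)
    return 1.0 / (1.0 + np.exp(-clf.decision_function(X)))


def _as_matrix(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), features.columns.to_numpy()
    if hasattr(features, "values") and hasattr(features, "feature_ids"):
        return np.asarray(features.values, dtype=float), features.feature_ids
    X = np.asarray(features, dtype=float)
    return X, np.array([f"f{j}" for j in range(X.shape[1])], dtype=object)


def train_and_evaluate(
    features,
    labels,
    models: dict | None = None,
    n_splits: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 1,
    threshold: float = 0.5,
) -> MetricsTable:
    """Repeated stratified-split evaluation of the classifier panel.

    Per split and model: fit on the training part, score the held-out part,
    and compute the eight metrics at the 0.5 operating point.  Split seeds run
    ``seed .. seed + n_splits - 1``.  Splits whose test part is single-class
    are recorded as missing for all metrics and excluded from the means.
    """
    X, _ = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if models is None:
        models = default_models()
    rows = []
    n_excluded = {name: 0 for name in models}
    for s in range(n_splits):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=seed + s
        )
        degenerate = len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2
        for name, proto in models.items():
            if degenerate:
                n_excluded[name] += 1
                rows.append({"split": s, "model": name,
                             **{m: np.nan for m in METRIC_NAMES}})
                continue
            clf = clone(proto)
            if "random_state" in clf.get_params():
                clf.set_params(random_state=seed + s)
            clf.fit(X_tr, y_tr)
            rows.append({"split": s, "model": name,
                         **compute_metrics(y_te, _scores(clf, X_te), threshold)})
    per_split = pd.DataFrame(rows)
    summary = per_split.groupby("model")[METRIC_NAMES].mean().loc[list(models)]
    return MetricsTable(per_split=per_split, summary=summary, n_excluded=n_excluded)


def compare_models_dunnett(metrics: MetricsTable, metric: str = "AUC") -> ModelComparison:
    """One-way ANOVA on per-split AUCs, then Dunnett tests vs the best model."""
    wide = metrics.per_split.pivot(index="split", columns="model", values=metric).dropna()
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 models to compare")
    if wide.shape[0] < 10:
        raise ValueError("need at least 10 complete splits to compare models")
    means = wide.mean()
    ref = means.idxmax()
    others = [m for m in wide.columns if m != ref]
    F, p = scipy.stats.f_oneway(*[wide[m].to_numpy() for m in wide.columns])
    res = scipy.stats.dunnett(*[wide[m].to_numpy() for m in others],
                              control=wide[ref].to_numpy())
    comparisons = pd.DataFrame({
        "model": others,
        "mean": [means[m] for m in others],
        "diff_vs_reference": [means[m] - means[ref] for m in others],
        "statistic": res.statistic,
        "p_adj": res.pvalue,
    })
    return ModelComparison(reference=ref, anova_F=float(F), anova_p=float(p),
                           comparisons=comparisons)


def km_check_of_predictions(surv: SurvivalData, y_true, y_pred,
                            cutoff_months: float | None = 60.0):
    """Log-rank tests of survival split by true and by predicted labels.

    Returns ``(logrank_true, logrank_pred)`` for side-by-side reporting: a
    useful predictor reproduces the survival separation of the true grouping.
    """
    from .stats import km_logrank

    _, lr_true = km_logrank(surv, np.asarray(y_true), cutoff_months=cutoff_months)
    _, lr_pred = km_logrank(surv, np.asarray(y_pred), cutoff_months=cutoff_months)
    return lr_true, lr_pred
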