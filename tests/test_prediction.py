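import numpy as np
import pandas as pd
import pytest

from owclust.datatypes import SurvivalData
from owclust.prediction import (
    METRIC_NAMES,
    MetricsTable,
    compare_models_dunnett,
    compute_metrics,
    km_check_of_predictions,
    stability_select,
    train_and_evaluate,
)
from owclust.simulate import generate_logistic_design


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = np.array([1, 0, 1, 0, 1])
        m = compute_metrics(y, y.astype(float))
        for name in METRIC_NAMES:
            assert m[name] == pytest.approx(1.0)

    def test_always_positive_predictor(self):
        y = np.array([1, 1, 0, 0])
        m = compute_metrics(y, np.full(4, 0.9))
        assert m["Sp"] == 0.0
        assert m["G_means"] == 0.0
        assert m["MCC"] == 0.0

    def test_auc_from_concordant_pairs(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m["AUC"] == pytest.approx(0.75)  # 3 of 4 positive-negative pairs

    def test_reported_lr_row_identities(self):
        # split-averaged Se and Sp reproduce the published Youden index
        se, sp = 0.744, 0.655
        assert se + sp - 1 == pytest.approx(0.399, abs=5e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            compute_metrics([1, 1, 1], [0.2, 0.5, 0.9])

    def test_identities_on_random_confusions(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            score = rng.random(n)
            m = compute_metrics(y, score)
            assert m["Youden"] == pytest.approx(m["Se"] + m["Sp"] - 1, abs=1e-12)
            assert m["G_means"] == pytest.approx(np.sqrt(m["Se"] * m["Sp"]), abs=1e-12)
            pred = (score >= 0.5).astype(int)
            if len(np.unique(pred)) == 2:  # phi == Pearson r of binary vectors
                assert m["MCC"] == pytest.approx(np.corrcoef(pred, y)[0, 1], abs=1e-10)


class TestStabilitySelect:
    def test_duplicate_of_signal_feature_union_selected(self):
        X, y, idx = generate_logistic_design(200, 20, 3, coef=1.5, seed=2)
        X = np.column_stack([X, X[:, idx[0]]])  # exact duplicate of a signal column
        res = stability_select(X, y, n_splits=10, seed=1)
        names = np.asarray(res.frequency.index)
        pair = {names[idx[0]], names[-1]}
        assert pair & set(res.selected)

    def test_requires_both_classes(self, rng):
        X = rng.normal(size=(50, 5))
        with pytest.raises(ValueError, match="binary|class"):
            stability_select(X, np.ones(50, dtype=int), n_splits=2)

    def test_frequencies_bounded(self):
        X, y, _ = generate_logistic_design(120, 10, 2, seed=3)
        res = stability_select(X, y, n_splits=5, seed=1)
        assert np.all((res.frequency >= 0) & (res.frequency <= 1))
        assert res.selected == list(res.frequency.index[res.frequency >= res.threshold])


class TestTrainAndEvaluate:
    def test_separable_data_all_metrics_one(self, rng):
        y = np.repeat([0, 1], 40)
        X = y[:, None] * 10.0 + rng.normal(0, 0.01, size=(80, 3))
        table = train_and_evaluate(X, y, n_splits=5, seed=1)
        vals = table.per_split[METRIC_NAMES].to_numpy()
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_null_features_auc_near_half(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(120, 5))
        y = rng.integers(0, 2, size=120)
        table = train_and_evaluate(X, y, models={"LR": LogisticRegression(max_iter=500)},
                                   n_splits=200, seed=1)
        assert 0.45 <= table.summary.loc["LR", "AUC"] <= 0.55

    def test_degenerate_test_split_recorded_missing(self, rng):
        # 3 positives in 40 samples: some 20 % test splits hold a single class
        y = np.zeros(40, dtype=int)
        y[:3] = 1
        X = rng.normal(size=(40, 4))
        X[y == 1] += 3
        from sklearn.neighbors import KNeighborsClassifier

        table = train_and_evaluate(X, y, models={"kNN": KNeighborsClassifier(3)},
                                   n_splits=30, seed=1)
        assert table.per_split["AUC"].notna().sum() + table.n_excluded["kNN"] == 30
        assert np.isfinite(table.summary.loc["kNN", "AUC"])


def _fake_metrics(aucs_by_model):
    rows = []
    for model, aucs in aucs_by_model.items():
        for s, a in enumerate(aucs):
            rows.append({"split": s, "model": model, "AUC": a,
                         **{m: 0.5 for m in METRIC_NAMES if m != "AUC"}})
    per_split = pd.DataFrame(rows)
    summary = per_split.groupby("model")[METRIC_NAMES].mean()
    return MetricsTable(per_split=per_split, summary=summary, n_excluded={})


class TestDunnett:
    def test_identical_models_not_significant(self):
        aucs = np.linspace(0.6, 0.8, 50)
        comp = compare_models_dunnett(_fake_metrics({"A": aucs, "B": aucs}))
        assert comp.anova_F == pytest.approx(0.0, abs=1e-12)
        assert np.all(comp.comparisons["p_adj"] > 0.9)

    def test_shifted_model_strongly_significant(self, rng):
        base = 0.7 + rng.normal(0, 0.02, size=100)
        comp = compare_models_dunnett(_fake_metrics({
            "best": base + 0.1, "b": base, "c": base + rng.normal(0, 0.02, 100),
        }))
        assert comp.reference == "best"
        assert np.all(comp.comparisons["p_adj"] < 1e-3)

    def test_comparison_count_is_models_minus_one(self, rng):
        comp = compare_models_dunnett(_fake_metrics({
            m: 0.7 + rng.normal(0, 0.05, 20) for m in ["A", "B", "C"]
        }))
        assert len(comp.comparisons) == 2


class TestKMCheck:
    def _surv(self, rng, n=100):
        g = rng.integers(0, 2, size=n)
        t = rng.exponential(np.where(g == 1, 6.0, 20.0)) + 1e-3
        return SurvivalData(t, np.ones(n, dtype=int),
                            [f"S{i}" for i in range(n)]), g

    def test_identical_predictions_give_equal_statistics(self, rng):
        surv, g = self._surv(rng)
        lr_true, lr_pred = km_check_of_predictions(surv, g, g.copy())
        assert lr_true.statistic == pytest.approx(lr_pred.statistic)

    def test_random_predictions_weaker_than_truth(self):
        ps_true, ps_pred = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            surv, g = self._surv(rng)
            lr_true, lr_pred = km_check_of_predictions(surv, g, rng.permutation(g))
            ps_true.append(lr_true.p_value)
            ps_pred.append(lr_pred.p_value)
        assert np.median(ps_pred) > np.median(ps_true)

    def test_single_group_predictions_error(self, rng):
        surv, g = self._surv(rng)
        with pytest.raises(ValueError, match="group"):
            km_check_of_predictions(surv, g, np.zeros_like(g))
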