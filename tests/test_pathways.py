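import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from owclust.pathways import (
    ActivityScores,
    PathwayWeightMatrix,
    contrast_activity,
    load_pathway_weights,
    mlm_activity,
    preprocess_expression,
)
from owclust.simulate import generate_pathway_expression


def _weights(W, pathways=None):
    W = pd.DataFrame(W)
    W.index = [f"g{i}" for i in range(W.shape[0])]
    W.columns = pathways or [f"P{j}" for j in range(W.shape[1])]
    return PathwayWeightMatrix(weights=W, retained={c: list(W.index) for c in W.columns})


def _expr(values, samples=None):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = samples or [f"s{j}" for j in range(df.shape[1])]
    from owclust.pathways import ExpressionMatrix

    return ExpressionMatrix(values=df)


class TestPreprocess:
    def test_duplicate_genes_averaged_before_transform(self):
        raw = pd.DataFrame([[2.0, 4.0], [6.0, 8.0]], index=["gA", "gA"],
                           columns=["s1", "s2"])
        out = preprocess_expression(raw)
        np.testing.assert_allclose(out.values.loc["gA"], np.log2([5.0, 7.0]) + 0)
        np.testing.assert_allclose(out.values.loc["gA"], np.log2(np.array([4.0, 6.0]) + 1))

    def test_gene_above_zero_threshold_removed(self):
        raw = pd.DataFrame(np.ones((3, 100)), index=["a", "b", "c"])
        raw.iloc[1, :31] = 0.0  # 31 % zeros
        out = preprocess_expression(raw)
        assert "b" not in out.values.index
        assert {"a", "c"} <= set(out.values.index)

    def test_log2_transform_hand_case(self):
        raw = pd.DataFrame([[0.5, 1.0, 3.0], [7.0, 15.0, 31.0], [1.0, 1.0, 1.0]])
        out = preprocess_expression(raw)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.log2(raw.to_numpy() + 1.0), atol=1e-12)

    def test_idempotent(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 10, size=(20, 8)))
        once = preprocess_expression(raw)
        twice = preprocess_expression(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            preprocess_expression(pd.DataFrame([[-1.0, 2.0]]))


class TestMLMActivity:
    def test_orthogonal_design_identity(self):
        # columns orthogonal to each other and to the intercept
        W = np.zeros((8, 2))
        W[:4, 0] = [1.0, 1.0, -1.0, -1.0]
        W[4:, 1] = [1.0, 1.0, -1.0, -1.0]
        expr = _expr(np.column_stack([W[:, 0]]))
        scores = mlm_activity(expr, _weights(W))
        assert abs(scores.coefficients.iloc[0, 0] - 1.0) < 1e-10
        assert abs(scores.coefficients.iloc[0, 1]) < 1e-10

    def test_matches_statsmodels_ols(self, rng):
        W = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 3))
        scores = mlm_activity(_expr(Y), _weights(W))
        design = sm.add_constant(W)
        for s in range(3):
            fit = sm.OLS(Y[:, s], design).fit()
            np.testing.assert_allclose(scores.coefficients.iloc[s].to_numpy(),
                                       fit.params[1:], atol=1e-8)
            np.testing.assert_allclose(scores.t_values.iloc[s].to_numpy(),
                                       fit.tvalues[1:], atol=1e-8)

    def test_recovers_activity_signs(self, rng):
        W = rng.normal(size=(120, 4))
        A = rng.choice([-2.0, 2.0], size=(4, 40))
        expr_vals = generate_pathway_expression(W, A, noise_sd=0.1, seed=9)
        scores = mlm_activity(_expr(expr_vals), _weights(W))
        match = np.sign(scores.t_values.to_numpy().T) == np.sign(A)
        assert match.mean() > 0.95

    def test_rank_deficient_weights_name_collinear_pathways(self, rng):
        w = rng.normal(size=(10, 1))
        W = np.column_stack([w, 2 * w, rng.normal(size=(10, 1))])
        with pytest.raises(ValueError, match="P0.*P1|P1.*P0|collinear"):
            mlm_activity(_expr(rng.normal(size=(10, 2))), _weights(W))

    def test_single_pathway_rejected(self, rng):
        with pytest.raises(ValueError, match="2 pathways"):
            mlm_activity(_expr(rng.normal(size=(5, 2))), _weights(rng.normal(size=(5, 1))))


class TestLoadWeights:
    def test_top_n_by_p_value_retained(self, rng):
        rows = []
        for i in range(150):
            rows.append({"gene": f"g{i}", "pathway": "P0", "weight": 1.0,
                         "p_value": i / 150})
        tab = pd.DataFrame(rows)
        W = load_pathway_weights(tab, top_n=100)
        assert len(W.retained["P0"]) == 100
        assert (W.weights["P0"] != 0).sum() == 100
        # the retained genes are the smallest-p ones
        assert set(W.retained["P0"]) == {f"g{i}" for i in range(100)}


class TestContrast:
    def _scores(self, values, samples=None):
        df = pd.DataFrame(values, columns=["P0", "P1"])
        df.index = samples or [f"s{j}" for j in range(len(df))]
        return ActivityScores(t_values=df, coefficients=df)

    def test_reference_swap_flips_signs_exactly(self, rng):
        scores = self._scores(rng.normal(size=(30, 2)))
        labels = np.array([1] * 15 + [2] * 15)
        a = contrast_activity(scores, labels, reference_subtype=2)
        b = contrast_activity(scores, labels, reference_subtype=1)
        np.testing.assert_allclose(a["t"], -b["t"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_null_scores_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = self._scores(rng.normal(size=(60, 2)))
            labels = np.array([1] * 30 + [2] * 30)
            res = contrast_activity(scores, labels, reference_subtype=2)
            hits += (res["p_adj"] < 0.05).any()
        assert hits <= 1

    def test_shifted_pathway_detected(self):
        found = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(100, 2))
            vals[50:, 0] += 3.0
            res = contrast_activity(self._scores(vals),
                                    np.array([1] * 50 + [2] * 50), 2)
            found += res.loc["P0", "p_adj"] < 0.05 and res.loc["P1", "p_adj"] >= 0.05
        assert found >= 19

    def test_adjusted_never_below_raw(self, rng):
        scores = self._scores(rng.normal(size=(40, 2)))
        res = contrast_activity(scores, np.array([1] * 20 + [2] * 20), 2)
        assert np.all(res["p_adj"] >= res["p"] - 1e-12)

    def test_tiny_subtype_rejected(self, rng):
        scores = self._scores(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="2 samples"):
            contrast_activity(scores, np.array([1, 1, 1, 1, 2]), 2)
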