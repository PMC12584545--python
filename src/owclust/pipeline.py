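"""End-to-end pipeline: subtype discovery, evaluation, enrichment, prediction.

Stage order mirrors the analysis workflow: cluster-number selection ->
consensus clustering -> subtype evaluation -> feature enrichment ->
stability selection -> biomarker prediction -> (optional) pathway scoring.
Every artifact is a delimited-text or JSON file under the output directory;
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as owio
from .enrichment import differential_features, flag_expression, hypergeometric_enrichment
from .model import SurvClust
from .pathways import contrast_activity, load_pathway_weights, mlm_activity, preprocess_expression
from .prediction import compare_models_dunnett, stability_select, train_and_evaluate
from .stats import chi_square_test, fit_cox_multivariable, km_logrank, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and tuning knobs for a full pipeline run."""

    features: list
    survival: str
    outdir: str
    marker: str | None = None
    clinical: str | None = None
    expression: str | None = None
    weights: str | None = None
    k: int | None = None               # fixed cluster count; None = select via CPI+Gap
    k_min: int = 2
    k_max: int = 8
    n_rounds: int = 50
    n_folds: int = 3
    n_starts: int = 100
    cpi_splits: int = 20
    gap_B: int = 50
    z_threshold: float = 0.6
    fdr_alpha: float = 0.05
    freq_threshold: float = 0.10
    cutoff_months: float = 60.0
    stability_splits: int = 100
    eval_splits: int = 1000
    reference_subtype: int = 2
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        paths = list(self.features) + [self.survival]
        for opt in (self.marker, self.clinical, self.expression, self.weights):
            if opt is not None:
                paths.append(opt)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if not 0 < self.fdr_alpha < 1 or not 0 < self.freq_threshold < 1:
            raise ValueError("fdr_alpha and freq_threshold must lie in (0, 1)")
        if self.z_threshold <= 0 or self.cutoff_months <= 0:
            raise ValueError("z_threshold and cutoff_months must be positive")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")


def _dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            run_logger = logging.getLogger("owclust.run")
            run_logger.info("stage %s: start", name)
            try:
                result = fn(*a, **kw)
            except Exception as exc:
                run_logger.error("stage %s: failed (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            run_logger.info("stage %s: done", name)
            return result
        return inner
    return wrap


def _start_run_log(config: PipelineConfig, outdir: Path) -> logging.Logger:
    """Stage log to stderr and <outdir>/run.log with seed and config hash."""
    import hashlib

    from . import __version__

    run_logger = logging.getLogger("owclust.run")
    run_logger.setLevel(logging.INFO)
    for h in list(run_logger.handlers):  # fresh file per run
        run_logger.removeHandler(h)
        h.close()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    run_logger.addHandler(handler)
    digest = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    run_logger.info("owclust %s  seed=%d  config_hash=%s", __version__,
                    config.seed, digest)
    return run_logger


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_logger = _start_run_log(config, outdir)

    blocks = [owio.read_feature_matrix(p) for p in config.features]
    surv = owio.read_survival(config.survival)
    model = SurvClust(blocks, surv)

    # --- cluster-number selection -------------------------------------- #
    k = config.k
    if k is None:
        ksel = _stage("select-k")(model.select_k)(
            range(config.k_min, config.k_max + 1), m=config.cpi_splits,
            B=config.gap_B, seed=config.seed, n_starts=config.n_starts,
        )
        _dump_json({
            "k_grid": ksel.k_grid, "cpi_score": ksel.cpi_score,
            "gap_score": ksel.gap_score, "combined": ksel.combined,
            "k_selected": ksel.k_selected,
        }, outdir / "kselect.json")
        k = ksel.k_selected
        logger.info("selected k = %d", k)

    # --- consensus clustering ------------------------------------------ #
    res = _stage("cluster")(model.fit)(
        k, n_rounds=config.n_rounds, n_folds=config.n_folds,
        seed=config.seed, n_starts=config.n_starts,
    )
    labels_df = res.to_frame()
    labels_df.index.name = "sample_id"
    labels_df.to_csv(outdir / "labels.tsv", sep="\t")
    labels = res.labels

    # --- subtype evaluation --------------------------------------------- #
    @_stage("evaluate")
    def evaluate():
        report = {"k": k, "cluster_sizes": labels.value_counts().sort_index().to_dict()}
        _, lr = km_logrank(surv, labels.reindex(surv.sample_ids).to_numpy(),
                           cutoff_months=config.cutoff_months)
        report["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p_value}
        cov = pd.get_dummies(
            labels.reindex(surv.sample_ids).astype("category"),
            prefix="subtype", drop_first=True,
        ).astype(float)
        if config.clinical:
            clin = owio._read_table(config.clinical).reindex(surv.sample_ids)
            report["clinical"] = {}
            for col in clin.columns:
                vals = clin[col]
                lab = labels.reindex(surv.sample_ids)
                if vals.dtype.kind in "fiu" and vals.nunique() > 5:
                    r = kruskal_wallis(vals.to_numpy(dtype=float), lab.to_numpy())
                    report["clinical"][col] = {"test": "kruskal", "H": r.statistic,
                                               "df": r.df, "p": r.p_value}
                else:
                    tab = pd.crosstab(vals, lab)
                    r = chi_square_test(tab.to_numpy())
                    report["clinical"][col] = {"test": "chi2", "chi2": r.statistic,
                                               "df": r.df, "p": r.p_value}
                    cov[f"clin_{col}"] = pd.get_dummies(
                        vals.astype("category"), drop_first=True
                    ).iloc[:, 0].astype(float) if vals.nunique() == 2 else np.nan
            cov = cov.dropna(axis=1)
        try:
            cox = fit_cox_multivariable(surv, cov)
            report["cox"] = {
                "table": json.loads(cox.table.to_json(orient="index")),
                "epv": cox.epv,
                "schoenfeld_global_p": cox.schoenfeld_global_p,
            }
        except ValueError as exc:
            report["cox"] = {"error": str(exc)}
        _dump_json(report, outdir / "evaluation.json")

    evaluate()

    # --- differential features & enrichment ----------------------------- #
    @_stage("enrich")
    def enrich():
        lab = labels.reindex(model._canon_ids).to_numpy()
        diff = differential_features(model.blocks, lab, alpha=config.fdr_alpha)
        diff.table.to_csv(outdir / "differential_features.tsv", sep="\t", index=False)
        frames = []
        for block in model.blocks:
            flags = flag_expression(block, threshold=config.z_threshold)
            frames.append(hypergeometric_enrichment(flags, lab, alpha=config.fdr_alpha))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False)
        return diff

    diff = enrich()

    # --- biomarker prediction -------------------------------------------- #
    if config.marker:
        @_stage("stability-select")
        def select():
            marker = owio.read_column(config.marker).reindex(model._canon_ids)
            feats = []
            for m_i, block in enumerate(model.blocks):
                keep = diff.selected_features(modality=m_i)
                feats.append(block.to_dataframe()[keep])
            mat = pd.concat(feats, axis=1)
            if mat.shape[1] == 0:
                raise ValueError("no differential features to select from")
            sel = stability_select(mat, marker.to_numpy(dtype=int),
                                   n_splits=config.stability_splits,
                                   freq_threshold=config.freq_threshold,
                                   seed=config.seed)
            sel.frequency.rename_axis("feature").to_csv(outdir / "stability_frequency.tsv", sep="\t")
            return mat, marker, sel

        mat, marker, sel = select()

        @_stage("predict")
        def predict():
            if not sel.selected:
                raise ValueError("stability selection kept no features")
            metrics = train_and_evaluate(mat[sel.selected], marker.to_numpy(dtype=int),
                                         n_splits=config.eval_splits, seed=config.seed)
            metrics.per_split.to_csv(outdir / "metrics_per_split.tsv", sep="\t", index=False)
            _dump_json(json.loads(metrics.summary.to_json(orient="index")),
                       outdir / "metrics_summary.json")
            comp = compare_models_dunnett(metrics)
            _dump_json({
                "reference": comp.reference, "anova_F": comp.anova_F,
                "anova_p": comp.anova_p,
                "comparisons": json.loads(comp.comparisons.to_json(orient="records")),
            }, outdir / "model_comparison.json")

        predict()

    # --- pathway activity ------------------------------------------------ #
    if config.expression and config.weights:
        @_stage("pathway-score")
        def pathway():
            expr = preprocess_expression(
                owio.read_expression(config.expression))
            weights = load_pathway_weights(owio.read_weights_table(config.weights))
            scores = mlm_activity(expr, weights)
            lab = labels.reindex(scores.t_values.index)
            contrast = contrast_activity(scores, lab.to_numpy(), config.reference_subtype)
            _dump_json(json.loads(contrast.to_json(orient="index")),
                       outdir / "pathways.json")

        pathway()

    return outdir
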