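"""Delimited-text readers and writers for the pipeline's tabular artifacts.

All tables are plain delimited text (tab or comma, sniffed on read) with the
sample identifier in the first column.  Floats are written with 17
significant digits and parsed in round-trip mode, so write -> read is
bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ModalityMatrix, SurvivalData
from .simulate import SyntheticCohort

__all__ = ["read_feature_matrix", "read_survival", "read_column", "read_weights_table",
           "write_feature_matrix", "write_survival", "write_cohort"]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    # tab wins when present; otherwise fall back to comma
    return "\t" if "\t" in header else ","


def _read_table(path) -> pd.DataFrame:
    # round_trip parsing keeps write -> read bit-exact for 17-digit floats
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.map(str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated sample id(s) in {path}: {dup}")
    return df


def read_feature_matrix(path) -> ModalityMatrix:
    """Read a samples x features block (first column sample_id, header names)."""
    df = _read_table(path)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ValueError(f"non-numeric value in {path} at row {row!r}, column {col!r}")
        df[col] = numeric
    return ModalityMatrix.from_dataframe(df)


def read_survival(path) -> SurvivalData:
    """Read a survival table with columns sample_id, time, event."""
    df = _read_table(path)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival file {path} lacks column(s) {sorted(missing)}")
    return SurvivalData.from_dataframe(df)


def read_column(path, column: str | None = None) -> pd.Series:
    """Read a per-sample label/marker file (sample_id + one value column)."""
    df = _read_table(path)
    if column is None:
        column = df.columns[0]
    return df[column]


def read_weights_table(path) -> pd.DataFrame:
    """Read a long pathway-weights table (gene, pathway, weight[, p_value])."""
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    required = {"gene", "pathway", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"weights file {path} needs columns {sorted(required)}")
    return df


def write_feature_matrix(X: ModalityMatrix, path, sep: str = "\t") -> None:
    df = X.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_survival(surv: SurvivalData, path, sep: str = "\t") -> None:
    df = surv.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_cohort(cohort: SyntheticCohort, outdir, sep: str = "\t") -> dict:
    """Write a synthetic cohort as the pipeline's standard input files.

    Emits one features file per modality plus survival, marker and truth
    tables; returns a dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"features": []}
    for i, block in enumerate(cohort.feature_blocks):
        p = outdir / f"features_modality{i + 1}.tsv"
        write_feature_matrix(block, p, sep=sep)
        paths["features"].append(p)
    paths["survival"] = outdir / "survival.tsv"
    write_survival(cohort.survival, paths["survival"], sep=sep)
    ids = cohort.sample_ids
    marker = pd.DataFrame({"marker": cohort.marker}, index=ids)
    marker.index.name = "sample_id"
    paths["marker"] = outdir / "marker.tsv"
    marker.to_csv(paths["marker"], sep=sep)
    truth = pd.DataFrame({"true_label": cohort.true_labels}, index=ids)
    truth.index.name = "sample_id"
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep=sep)
    return paths


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column gene id)."""
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                       float_precision="round_trip")
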