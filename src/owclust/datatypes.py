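"""Core containers for multimodal feature blocks, survival data and distances.

Rows are always samples; labels are 1-based cluster indices.  Containers are
thin dataclasses around numpy arrays plus ordered sample/feature identifiers,
convertible to/from :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModalityMatrix",
    "SurvivalData",
    "FeatureWeights",
    "DistanceMatrix",
    "IntegratedDistance",
    "Embedding",
    "ClusteringSolution",
]


def _as_str_ids(ids: Sequence) -> np.ndarray:
    return np.asarray([str(i) for i in ids], dtype=object)


@dataclass
class ModalityMatrix:
    """One feature block (samples x features) with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
    sample_ids, feature_ids : ordered identifiers
    standardized : whether columns are cohort z-scores
    """

    values: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_ids(self.sample_ids)
        self.feature_ids = _as_str_ids(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed in a ModalityMatrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "ModalityMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy(),
                   standardized=standardized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def take_samples(self, idx) -> "ModalityMatrix":
        return replace(self, values=self.values[idx], sample_ids=self.sample_ids[idx])


@dataclass
class SurvivalData:
    """Per-sample right-censored time-to-event data (event 1 = death)."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.sample_ids = _as_str_ids(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.sample_ids)):
            raise ValueError("time, event and sample_ids must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       event_col: str = "event") -> "SurvivalData":
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy(), df.index.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event}, index=self.sample_ids)

    def take_samples(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx], self.sample_ids[idx])


@dataclass
class FeatureWeights:
    """Per-feature |log hazard ratio| weights from univariate Cox fits."""

    beta: np.ndarray
    weight: np.ndarray
    converged: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.converged = np.asarray(self.converged, dtype=bool)
        self.feature_ids = _as_str_ids(self.feature_ids)
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    def to_series(self) -> pd.Series:
        return pd.Series(self.weight, index=self.feature_ids, name="weight")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_ids(self.sample_ids)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square and match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric (tolerance 1e-10)")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class IntegratedDistance(DistanceMatrix):
    """Modality-averaged weighted distance matrix I_w = sum_m gamma_m D_m."""

    gammas: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        super().__post_init__()
        self.gammas = np.asarray(self.gammas, dtype=float)
        if not np.isclose(self.gammas.sum(), 1.0):
            raise ValueError("modality mixing weights must sum to 1")

    @property
    def n_modalities(self) -> int:
        return len(self.gammas)


@dataclass
class Embedding:
    """Classical-MDS coordinates realising a distance matrix in Euclidean space."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.sample_ids = _as_str_ids(self.sample_ids)

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusteringSolution:
    """Consensus subtype labels with per-round labels and diagnostics.

    ``consensus_labels`` are 1-based; ``agreement`` is the per-sample fraction
    of cross-validation rounds voting the consensus label.
    """

    k: int
    consensus_labels: np.ndarray
    round_labels: np.ndarray  # (n_rounds, n_samples), aligned to round 1
    agreement: np.ndarray
    centroids: np.ndarray
    wss: float
    sample_ids: np.ndarray

    def __post_init__(self):
        self.consensus_labels = np.asarray(self.consensus_labels, dtype=int)
        labs = np.unique(self.consensus_labels)
        if labs.min() < 1 or labs.max() > self.k:
            raise ValueError("consensus labels must lie in 1..k")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"consensus_label": self.consensus_labels, "agreement": self.agreement},
            index=_as_str_ids(self.sample_ids),
        )
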