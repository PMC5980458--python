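"""Prevalence-balanced, distance-weighted training sets.

Model selection uses training sets of equal presence and background counts
(prevalence exactly 0.5), which removes the prevalence dependence of
threshold-based objectives such as TSS. Presences are bootstrap sampled
uniformly; backgrounds are bootstrap sampled with probability decaying in
the distance to the nearest presence, so absence conditions are contrasted
with presence conditions within the same geographical unit.

The decay is exponential, w(d) = exp(-d / lambda), with lambda defaulting
to the median nearest-presence distance over the background pool — a
scale-free choice exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError
from .variables import PRESENCE


@dataclass
class TrainingSet:
    """Balanced labelled records: ``records`` carries a binary ``label``."""

    records: pd.DataFrame
    n_presence: int
    n_background: int
    seed: int | None
    decay_scale: float

    def __post_init__(self) -> None:
        if self.n_presence != self.n_background:
            raise DataError("training sets must be prevalence-balanced")

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy(dtype=int)


def filter_complete(records: pd.DataFrame, candidate_variables) -> pd.DataFrame:
    """Keep only records with a value for every candidate variable."""
    candidate_variables = list(candidate_variables)
    missing_cols = [v for v in candidate_variables if v not in records.columns]
    if missing_cols:
        raise DataError(f"candidate variables not in records: {missing_cols}")
    mask = records[candidate_variables].notna().all(axis=1)
    out = records[mask]
    if out.empty:
        raise DataError("no record has values for all candidate variables")
    return out


def filter_juveniles(records: pd.DataFrame, length_cm_threshold: float = 15.0,
                     length_column: str = "length_cm") -> pd.DataFrame:
    """Keep presence records of juveniles (length strictly below threshold).

    Non-presence records carry no individual length and pass through
    unchanged; presence records without a length are dropped.
    """
    if length_column not in records.columns:
        raise ConfigurationError(f"length column {length_column!r} absent from records")
    is_presence = records["status"] == PRESENCE
    lengths = pd.to_numeric(records[length_column], errors="coerce")
    keep = ~is_presence | (lengths < length_cm_threshold)
    return records[keep]


def nearest_presence_distance(backgrounds: pd.DataFrame,
                              presences: pd.DataFrame) -> np.ndarray:
    """Euclidean distance from each background site to its closest presence."""
    tree = cKDTree(presences[["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(backgrounds[["x", "y"]].to_numpy(dtype=float), k=1)
    return np.asarray(d, dtype=float)


def background_weights(backgrounds: pd.DataFrame, presences: pd.DataFrame,
                       decay_scale: float | None = None) -> tuple[np.ndarray, float]:
    """Normalised exp(-d/lambda) selection weights and the lambda used.

    Distances are taken to the full presence pool, computed once; lambda
    defaults to the median nearest-presence distance (or 1 if that median
    is 0). ``decay_scale=inf`` gives uniform weights.
    """
    d = nearest_presence_distance(backgrounds, presences)
    if decay_scale is None:
        decay_scale = float(np.median(d))
        if decay_scale <= 0.0:
            decay_scale = 1.0
    if decay_scale <= 0.0:
        raise ConfigurationError("decay_scale must be positive")
    if np.isinf(decay_scale):
        w = np.ones(len(d))
    else:
        w = np.exp(-d / decay_scale)
    return w / w.sum(), float(decay_scale)


def sample_training_set(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    n_each: int = 25,
    decay_scale: float | None = None,
    seed: int | None = None,
) -> TrainingSet:
    """Bootstrap a balanced training set of ``n_each`` records per label.

    Presences are drawn uniformly with replacement; backgrounds with
    replacement, weighted by distance to the nearest presence (see
    :func:`background_weights`). Presences get label 1, backgrounds 0.
    """
    if n_each < 1:
        raise ConfigurationError("n_each must be >= 1")
    if presences.empty or backgrounds.empty:
        raise DataError("need at least one presence and one background record")

    rng = np.random.default_rng(seed)
    w, lam = background_weights(backgrounds, presences, decay_scale)

    p_idx = rng.choice(len(presences), size=n_each, replace=True)
    b_idx = rng.choice(len(backgrounds), size=n_each, replace=True, p=w)

    p = presences.iloc[p_idx].copy()
    p["label"] = 1
    b = backgrounds.iloc[b_idx].copy()
    b["label"] = 0
    records = pd.concat([p, b], ignore_index=True)
    return TrainingSet(records=records, n_presence=n_each, n_background=n_each,
                       seed=seed, decay_scale=lam)
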