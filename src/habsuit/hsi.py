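"""Suitability indices and their geometric-mean aggregation into an HSI.

The habitat suitability index of a site is the geometric mean of the
suitability indices of the model's variables at that site,

    HSI = (prod_j SI(x_j)) ** (1/m),

with m the number of contributing variables. The geometric mean encodes
limiting-factor behaviour: one unsuitable condition (SI = 0) cannot be
compensated by the others and forces HSI = 0. Variables without input data
at a site are dropped and m reduced accordingly, so sites with partial
covariates still get an HSI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .hpc import CategoricalHPC, TrapezoidHPC


def trapezoid_si(a1: float, a2: float, a3: float, a4: float, x):
    """Evaluate the trapezoidal suitability curve at ``x`` (scalar or array).

    0 outside [a1, a4]; linear rise on [a1, a2]; 1 on the plateau [a2, a3];
    linear fall on [a3, a4]. At a degenerate limb (a1 == a2 or a3 == a4) the
    plateau value 1 wins at the shared point, the limit of a shrinking
    trapezoid.
    """
    x = np.asarray(x, dtype=float)
    si = np.zeros(x.shape)
    on_plateau = (x >= a2) & (x <= a3)
    si[on_plateau] = 1.0
    if a2 > a1:
        rising = (x >= a1) & (x < a2)
        si[rising] = (x[rising] - a1) / (a2 - a1)
    if a4 > a3:
        falling = (x > a3) & (x <= a4)
        si[falling] = (a4 - x[falling]) / (a4 - a3)
    si[~np.isfinite(x)] = np.nan
    return si if si.shape else float(si)


def evaluate_si_continuous(hpc: TrapezoidHPC, x):
    """Suitability index of a trapezoid HPC at value(s) ``x``."""
    return trapezoid_si(hpc.a1, hpc.a2, hpc.a3, hpc.a4, x)


def evaluate_si_categorical(hpc: CategoricalHPC, cls) -> float:
    """Suitability index of a class; classes unseen in training score 0."""
    key = str(cls)
    if key not in hpc.si_by_class:
        warnings.warn(
            f"{hpc.variable}: class {key!r} not seen in training data; SI = 0",
            stacklevel=2,
        )
        return 0.0
    return hpc.si_by_class[key]


def evaluate_si(hpc, value):
    """Dispatch on HPC flavour; missing input (None/NaN) gives NaN."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    if isinstance(hpc, TrapezoidHPC):
        return float(evaluate_si_continuous(hpc, float(value)))
    return evaluate_si_categorical(hpc, value)


def geometric_mean_si(si_values) -> tuple[float, int]:
    """Geometric mean over the observed (non-NaN) SIs and the count used.

    Computed through logarithms with a zero short-circuit so products of
    many small SIs cannot underflow. Returns ``(nan, 0)`` when no SI is
    observed.
    """
    si = np.asarray(si_values, dtype=float)
    si = si[~np.isnan(si)]
    if si.size == 0:
        return float("nan"), 0
    if np.any(si == 0.0):
        return 0.0, int(si.size)
    return float(np.exp(np.mean(np.log(si)))), int(si.size)


def predict_presence(hsi, threshold: float):
    """Binary presence from HSI: 1 iff HSI >= threshold (ties are presence)."""
    hsi_arr = np.asarray(hsi, dtype=float)
    pred = (hsi_arr >= threshold).astype(int)
    return pred if pred.shape else int(pred)


@dataclass
class SiteSuitability:
    """Per-site model output: SIs, their geometric mean, and the count used."""

    site_id: object
    si_by_variable: dict
    hsi: float
    m_used: int


@dataclass
class SuitabilityModel:
    """A set of fitted HPCs over distinct variables plus a decision threshold."""

    hpcs: list
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if not self.hpcs:
            raise DataError("a suitability model needs at least one HPC")
        names = [h.variable for h in self.hpcs]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate variables in model: {names}")
        if not 0.0 <= self.threshold <= 1.0:
            raise DataError(f"threshold must be in [0, 1], got {self.threshold}")

    @property
    def variables(self) -> list[str]:
        return [h.variable for h in self.hpcs]

    def si_table(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-record SI of every model variable; NaN where input is missing."""
        out = {}
        for hpc in self.hpcs:
            if hpc.variable not in records.columns:
                out[hpc.variable] = np.full(len(records), np.nan)
                continue
            col = records[hpc.variable]
            if isinstance(hpc, TrapezoidHPC):
                out[hpc.variable] = trapezoid_si(
                    hpc.a1, hpc.a2, hpc.a3, hpc.a4, col.astype(float).to_numpy()
                )
            else:
                si_map = hpc.si_by_class
                out[hpc.variable] = np.array([
                    np.nan if pd.isna(v) else si_map.get(str(v), 0.0) for v in col
                ])
        return pd.DataFrame(out, index=records.index)

    def evaluate(self, records: pd.DataFrame) -> pd.DataFrame:
        """Evaluate every record: columns ``site_id, hsi, m_used, si_<var>...``.

        Records where no model variable is observed get ``hsi = NaN`` and
        ``m_used = 0``; they are reported with a warning, not fatal.
        """
        si = self.si_table(records)
        hsi, m_used = _aggregate_si_frame(si)
        result = pd.DataFrame({
            "site_id": records["site_id"].to_numpy() if "site_id" in records else records.index,
            "hsi": hsi,
            "m_used": m_used,
        }, index=records.index)
        for var in si.columns:
            result[f"si_{var}"] = si[var]
        n_failed = int((m_used == 0).sum())
        if n_failed:
            warnings.warn(
                f"{n_failed} record(s) had no observed model variable; HSI undefined",
                stacklevel=2,
            )
        return result

    def hsi(self, records: pd.DataFrame) -> np.ndarray:
        """HSI per record as a plain array."""
        hsi, _ = _aggregate_si_frame(self.si_table(records))
        return hsi

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return predict_presence(self.hsi(records), self.threshold)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "hpcs": [h.to_dict() for h in self.hpcs]}

    @classmethod
    def from_dict(cls, d: dict) -> "SuitabilityModel":
        from .hpc import hpc_from_dict
        return cls(hpcs=[hpc_from_dict(h) for h in d["hpcs"]],
                   threshold=float(d["threshold"]))


def _aggregate_si_frame(si: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    values = si.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    m_used = observed.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(observed & (values > 0), np.log(np.where(values > 0, values, 1.0)), 0.0)
        mean_log = np.where(m_used > 0, logs.sum(axis=1) / np.maximum(m_used, 1), np.nan)
        hsi = np.exp(mean_log)
    any_zero = (observed & (values == 0.0)).any(axis=1)
    hsi[any_zero] = 0.0
    hsi[m_used == 0] = np.nan
    return hsi, m_used


def compute_hsi(model: SuitabilityModel, record) -> SiteSuitability:
    """Evaluate one record (a mapping or a one-row DataFrame slice).

    The HSI is the geometric mean of the observed SIs; any SI = 0 forces
    HSI = 0; variables with missing input are dropped from m.
    """
    if isinstance(record, pd.DataFrame):
        if len(record) != 1:
            raise DataError("compute_hsi expects a single record")
        record = record.iloc[0]
    get = record.get if hasattr(record, "get") else record.__getitem__
    si_by_variable = {h.variable: evaluate_si(h, get(h.variable)) for h in model.hpcs}
    hsi, m_used = geometric_mean_si(list(si_by_variable.values()))
    return SiteSuitability(
        site_id=get("site_id") if hasattr(record, "get") else None,
        si_by_variable=si_by_variable,
        hsi=hsi,
        m_used=m_used,
    )
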