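"""Habitat preference curves (HPCs) fitted from presence records.

A habitat preference curve maps one environmental variable to a suitability
index (SI) in [0, 1]. Continuous variables get a nonsymmetric trapezoid
described by four parameters ``a1 <= a2 <= a3 <= a4``: the fitted range
``[a1, a4]`` is the observed extent of presence values (approximating the
fundamental niche), the plateau ``[a2, a3]`` is the inter-quartile optimum.
Categorical and binary variables get one SI per class from the ratio of the
class's share among presences to its share in the full dataset, normalised
so the most preferred class scores 1.

All fits are bootstrapped (resampling the presence records with replacement,
at the original sample size) and summarised by per-parameter medians, so the
replicate spread carries the sampling uncertainty of the curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

#: Order of the trapezoid parameters in replicate arrays.
TRAPEZOID_PARAMS = ("a1", "a2", "a3", "a4")


@dataclass
class TrapezoidHPC:
    """Fitted trapezoidal preference curve for a continuous variable.

    ``replicates`` has shape ``(n_boot, 4)`` with columns a1, a2, a3, a4;
    the summary parameters are per-column medians of the replicates.
    """

    variable: str
    a1: float
    a2: float
    a3: float
    a4: float
    replicates: np.ndarray = field(default=None, repr=False)
    n_boot: int = 0

    kind = "trapezoid"

    def __post_init__(self) -> None:
        if not self.a1 <= self.a2 <= self.a3 <= self.a4:
            raise DataError(
                f"{self.variable}: trapezoid parameters must satisfy "
                f"a1 <= a2 <= a3 <= a4, got {(self.a1, self.a2, self.a3, self.a4)}"
            )
        if self.replicates is None:
            self.replicates = np.array([[self.a1, self.a2, self.a3, self.a4]])
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.n_boot == 0:
            self.n_boot = len(self.replicates)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a1, self.a2, self.a3, self.a4)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            "params": list(self.params),
            "replicates": self.replicates.tolist(),
            "n_boot": int(self.n_boot),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrapezoidHPC":
        a1, a2, a3, a4 = d["params"]
        return cls(
            variable=d["variable"],
            a1=a1, a2=a2, a3=a3, a4=a4,
            replicates=np.asarray(d["replicates"], dtype=float),
            n_boot=int(d["n_boot"]),
        )


@dataclass
class CategoricalHPC:
    """Fitted class-wise preference table for a categorical/binary variable."""

    variable: str
    si_by_class: dict
    replicates: list = field(default=None, repr=False)
    n_boot: int = 0

    kind = "categorical"

    def __post_init__(self) -> None:
        self.si_by_class = {str(k): float(v) for k, v in self.si_by_class.items()}
        for cls_, si in self.si_by_class.items():
            if not 0.0 <= si <= 1.0:
                raise DataError(f"{self.variable}: SI of class {cls_!r} outside [0, 1]")
        if abs(max(self.si_by_class.values()) - 1.0) > 1e-12:
            raise DataError(f"{self.variable}: maximal class SI must be 1")
        if self.replicates is None:
            self.replicates = [dict(self.si_by_class)]
        if self.n_boot == 0:
            self.n_boot = len(self.replicates)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            "si_by_class": dict(self.si_by_class),
            "replicates": [dict(r) for r in self.replicates],
            "n_boot": int(self.n_boot),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalHPC":
        return cls(
            variable=d["variable"],
            si_by_class=d["si_by_class"],
            replicates=d["replicates"],
            n_boot=int(d["n_boot"]),
        )


def hpc_from_dict(d: dict):
    """Reconstruct either HPC flavour from its JSON dictionary."""
    if d.get("kind") == "trapezoid":
        return TrapezoidHPC.from_dict(d)
    if d.get("kind") == "categorical":
        return CategoricalHPC.from_dict(d)
    raise DataError(f"unknown HPC kind {d.get('kind')!r}")


def save_hpcs(hpcs, path) -> None:
    with open(path, "w") as fh:
        json.dump([h.to_dict() for h in hpcs], fh, indent=1)


def load_hpcs(path) -> list:
    with open(path) as fh:
        return [hpc_from_dict(d) for d in json.load(fh)]


def _trapezoid_stats(values: np.ndarray) -> np.ndarray:
    # min, 25th percentile, 75th percentile, max; percentiles use linear
    # interpolation between order statistics
    return np.array([
        values.min(),
        np.percentile(values, 25),
        np.percentile(values, 75),
        values.max(),
    ])


def fit_trapezoid(
    presence_values,
    variable: str = "",
    n_boot: int = 200,
    seed: int | None = None,
    resample: bool = True,
) -> TrapezoidHPC:
    """Fit a trapezoid HPC from the presence values of one variable.

    Each bootstrap resamples the presence values with replacement at the
    original sample size and records (min, p25, p75, max); the summary
    parameters are the per-parameter medians over the replicates. Pass
    ``resample=False`` to disable resampling (every replicate is the
    original sample — the "identity bootstrap" used in exact tests).

    Parameters
    ----------
    presence_values:
        Environmental values at presence records; at least 2 finite values.
    n_boot:
        Number of bootstrap replicates (>= 1); 200 by default.
    seed:
        Seed for the bootstrap resampling.
    """
    values = np.asarray(presence_values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    values = np.sort(values[np.isfinite(values)])  # permutation-invariant fits
    if len(values) < 2:
        raise DataError("need at least 2 finite presence values to fit a trapezoid")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")

    if np.ptp(values) == 0.0:
        warnings.warn(
            f"all presence values identical for {variable or 'variable'}; "
            "degenerate trapezoid a1=a2=a3=a4",
            stacklevel=2,
        )

    if resample:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, 4))
        for b in range(n_boot):
            reps[b] = _trapezoid_stats(rng.choice(values, size=len(values), replace=True))
    else:
        reps = np.tile(_trapezoid_stats(values), (n_boot, 1))

    a1, a2, a3, a4 = np.median(reps, axis=0)
    return TrapezoidHPC(variable=variable, a1=a1, a2=a2, a3=a3, a4=a4,
                        replicates=reps, n_boot=n_boot)


def fit_categorical(
    presence_classes,
    all_classes,
    variable: str = "",
    n_boot: int = 200,
    seed: int | None = None,
    resample: bool = True,
    pseudo_count: float = 0.0,
) -> CategoricalHPC:
    """Fit a class-wise HPC from presence classes and the full-data classes.

    Per bootstrap of the presence records the raw preference of a class is
    (share among presences) / (share in the full data), then normalised by
    the maximal raw value so every replicate is a valid curve. The summary
    SI is the per-class median across replicates, renormalised to max 1.
    Classes never observed with the species present score exactly 0 unless
    ``pseudo_count`` > 0 adds that many virtual presence observations per
    class before computing shares.
    """
    presence = np.asarray([str(c) for c in presence_classes])
    data = np.asarray([str(c) for c in all_classes])
    if len(presence) == 0 or len(data) == 0:
        raise DataError("presence and full-data class lists must be non-empty")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")

    classes, data_counts = np.unique(data, return_counts=True)
    unknown = set(presence) - set(classes)
    if unknown:
        raise DataError(
            f"classes {sorted(unknown)} present in the presence set but absent "
            "from the full data: share ratio undefined"
        )
    data_share = data_counts / data_counts.sum()
    index = {c: i for i, c in enumerate(classes)}

    codes = np.fromiter((index[c] for c in presence), dtype=int, count=len(presence))
    rng = np.random.default_rng(seed)

    reps = np.empty((n_boot, len(classes)))
    for b in range(n_boot):
        sample = rng.choice(codes, size=len(codes), replace=True) if resample else codes
        counts = np.bincount(sample, minlength=len(classes)).astype(float)
        counts += pseudo_count
        share = counts / counts.sum()
        raw = share / data_share
        reps[b] = raw / raw.max()

    summary = np.median(reps, axis=0)
    summary = summary / summary.max()

    si_by_class = {c: float(s) for c, s in zip(classes, summary)}
    replicates = [
        {c: float(s) for c, s in zip(classes, row)} for row in reps
    ]
    return CategoricalHPC(variable=variable, si_by_class=si_by_class,
                          replicates=replicates, n_boot=n_boot)


@dataclass
class ConvergenceReport:
    """Running-median convergence diagnostic of a bootstrap."""

    parameters: tuple
    n_replicates: int
    relative_change: dict      # parameter -> relative change over the final 25%
    trajectories: dict         # parameter -> running-median array
    tolerance: float
    converged: bool
    insufficient: bool


def bootstrap_convergence(replicates, parameters=None, tolerance: float = 1e-3) -> ConvergenceReport:
    """Report whether the bootstrap medians have stabilised.

    For each parameter the running median across replicates is computed; the
    diagnostic is the spread of that trajectory over the final 25% of
    replicates, relative to the final median (absolute when the final median
    is ~0). Advisory only — it does not stop the bootstrap.
    """
    if isinstance(replicates, (list, tuple)) and replicates and isinstance(replicates[0], dict):
        parameters = tuple(replicates[0].keys())
        reps = np.array([[r[p] for p in parameters] for r in replicates], dtype=float)
    else:
        reps = np.asarray(replicates, dtype=float)
        if reps.ndim == 1:
            reps = reps[:, None]
        if parameters is None:
            parameters = TRAPEZOID_PARAMS[: reps.shape[1]] if reps.shape[1] <= 4 else \
                tuple(f"p{i}" for i in range(reps.shape[1]))
    n = len(reps)
    if n < 2:
        raise DataError("need at least 2 replicates for a convergence diagnostic")

    insufficient = n < 8  # fewer than two points in the final quarter
    trajectories = {}
    relative_change = {}
    tail = max(2, int(np.ceil(n * 0.25)))
    for j, p in enumerate(parameters):
        traj = np.array([np.median(reps[: i + 1, j]) for i in range(n)])
        trajectories[p] = traj
        window = traj[-tail:]
        scale = max(abs(traj[-1]), 1e-12)
        relative_change[p] = float((window.max() - window.min()) / scale)

    converged = (not insufficient) and all(v <= tolerance for v in relative_change.values())
    return ConvergenceReport(
        parameters=tuple(parameters),
        n_replicates=n,
        relative_change=relative_change,
        trajectories=trajectories,
        tolerance=tolerance,
        converged=converged,
        insufficient=insufficient,
    )
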