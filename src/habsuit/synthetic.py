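"""Virtual-species datasets with a known abiotic niche.

The generator builds site x date records over a planar landscape (uniform
coordinates in metres), draws environmental values from each variable's
support, and labels occurrence from a known *true niche*: trapezoidal
optima for informative continuous variables, class preference tables for
informative categorical ones, combined by the geometric mean into a true
HSI. Because the truth is known, every downstream stage — curve fitting,
variable selection, ensemble support — can be tested for recovery.

The niche is purely abiotic: no dispersal, no species interactions, no
spatial autocorrelation. Records labelled ``background`` are sites where no
presence was simulated, not confirmed absences, mirroring how monitoring
data are used in presence/background suitability modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .hsi import geometric_mean_si, trapezoid_si
from .variables import (
    BACKGROUND,
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    PRESENCE,
    RECORD_COLUMNS,
    VariableSpec,
    check_roster,
)

#: Occurrence rules: hard threshold on the true HSI, or a Bernoulli draw
#: with success probability equal to the true HSI.
THRESHOLD_RULE = "threshold"
BERNOULLI_RULE = "bernoulli"


@dataclass
class TrueNiche:
    """The data-generating niche of a virtual species.

    ``trapezoids`` maps informative continuous variables to their true
    (a1, a2, a3, a4); ``class_si`` maps informative categorical/binary
    variables to class -> true SI (each with at least one class at SI 1).
    The true HSI of a record is the geometric mean of its true SIs.
    """

    trapezoids: dict = field(default_factory=dict)
    class_si: dict = field(default_factory=dict)
    rule: str = THRESHOLD_RULE
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.rule not in (THRESHOLD_RULE, BERNOULLI_RULE):
            raise ConfigurationError(f"unknown occurrence rule {self.rule!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError("occurrence threshold must be in [0, 1]")
        for var, params in self.trapezoids.items():
            a1, a2, a3, a4 = params
            if not a1 <= a2 <= a3 <= a4:
                raise ConfigurationError(f"{var}: true trapezoid must be ordered")
        for var, si_map in self.class_si.items():
            sis = list(si_map.values())
            if not all(0.0 <= s <= 1.0 for s in sis):
                raise ConfigurationError(f"{var}: true SIs must lie in [0, 1]")
            if max(sis) != 1.0:
                raise ConfigurationError(f"{var}: at least one class must have SI 1")

    @property
    def variables(self) -> list[str]:
        return list(self.trapezoids) + list(self.class_si)

    def true_si(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-record true SI of every niche variable."""
        missing = [v for v in self.variables if v not in records.columns]
        if missing:
            raise ConfigurationError(f"niche references unknown variables: {missing}")
        out = {}
        for var, (a1, a2, a3, a4) in self.trapezoids.items():
            out[var] = trapezoid_si(a1, a2, a3, a4, records[var].astype(float).to_numpy())
        for var, si_map in self.class_si.items():
            out[var] = np.array([
                np.nan if pd.isna(v) else si_map.get(str(v), 0.0)
                for v in records[var]
            ])
        return pd.DataFrame(out, index=records.index)

    def true_hsi(self, records: pd.DataFrame) -> np.ndarray:
        si = self.true_si(records)
        return np.array([geometric_mean_si(row)[0] for row in si.to_numpy()])

    def to_dict(self) -> dict:
        return {
            "trapezoids": {k: list(v) for k, v in self.trapezoids.items()},
            "class_si": {k: dict(v) for k, v in self.class_si.items()},
            "rule": self.rule,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueNiche":
        return cls(
            trapezoids={k: tuple(v) for k, v in d.get("trapezoids", {}).items()},
            class_si={k: dict(v) for k, v in d.get("class_si", {}).items()},
            rule=d.get("rule", THRESHOLD_RULE),
            threshold=float(d.get("threshold", 0.6)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrueNiche":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_environment(
    n_sites: int,
    specs,
    spatial_extent=(0.0, 0.0, 10_000.0, 10_000.0),
    seed: int | None = None,
    class_weights: dict | None = None,
    beta_params: dict | None = None,
    start_date: str = "2010-01-01",
    date_span_days: int = 2000,
) -> pd.DataFrame:
    """Draw ``n_sites`` records over a rectangular landscape.

    Coordinates are uniform over ``spatial_extent = (xmin, ymin, xmax, ymax)``
    in metres. Continuous variables are uniform over their support unless
    ``beta_params[name] = (alpha, beta)`` requests a skewed landscape;
    categorical variables are uniform over their classes unless
    ``class_weights[name]`` gives per-class weights.
    """
    specs = check_roster(specs)
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    xmin, ymin, xmax, ymax = (float(v) for v in spatial_extent)
    if not (xmax > xmin and ymax > ymin):
        raise ConfigurationError("spatial extent must have positive area")

    rng = np.random.default_rng(seed)
    data = {
        "site_id": [f"s{i:05d}" for i in range(n_sites)],
        "x": rng.uniform(xmin, xmax, n_sites),
        "y": rng.uniform(ymin, ymax, n_sites),
        "date": pd.to_datetime(start_date)
        + pd.to_timedelta(rng.integers(0, date_span_days, n_sites), unit="D"),
        "status": np.full(n_sites, BACKGROUND, dtype=object),
    }
    for spec in specs:
        if spec.is_continuous:
            low, high = spec.support
            if beta_params and spec.name in beta_params:
                a, b = beta_params[spec.name]
                data[spec.name] = low + (high - low) * rng.beta(a, b, n_sites)
            else:
                data[spec.name] = rng.uniform(low, high, n_sites)
        else:
            weights = None
            if class_weights and spec.name in class_weights:
                w = np.asarray(class_weights[spec.name], dtype=float)
                weights = w / w.sum()
            data[spec.name] = rng.choice(list(spec.classes), size=n_sites, p=weights)
    return pd.DataFrame(data)


def simulate_occurrence(records: pd.DataFrame, niche: TrueNiche,
                        seed: int | None = None) -> pd.DataFrame:
    """Label each record presence/background from its true HSI.

    Under the threshold rule a record is a presence iff its true HSI reaches
    the niche threshold; under the Bernoulli rule presence is drawn with
    probability equal to the true HSI.
    """
    records = records.copy()
    hsi = niche.true_hsi(records)
    if niche.rule == THRESHOLD_RULE:
        present = hsi >= niche.threshold
    else:
        rng = np.random.default_rng(seed)
        present = rng.random(len(records)) < hsi
    records["status"] = np.where(present, PRESENCE, BACKGROUND)
    return records


def inject_missingness(
    records: pd.DataFrame,
    complete_fraction: float,
    per_variable_rates: dict | None = None,
    seed: int | None = None,
    default_rate: float = 0.5,
    variables: list | None = None,
) -> pd.DataFrame:
    """Blank out variable values outside a protected complete subset.

    ``ceil(complete_fraction * n)`` records, chosen at random independently
    of the occurrence label, are protected and keep all their values. Every
    other record loses each variable independently with that variable's
    rate (``per_variable_rates``, falling back to ``default_rate``).
    """
    if not 0.0 <= complete_fraction <= 1.0:
        raise ConfigurationError("complete_fraction must be in [0, 1]")
    rates = dict(per_variable_rates or {})
    for var, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missingness rate for {var!r} outside [0, 1]")
    records = records.copy()
    if complete_fraction >= 1.0:
        return records

    if variables is None:
        variables = [c for c in records.columns if c not in RECORD_COLUMNS]
    n = len(records)
    n_protected = math.ceil(complete_fraction * n)
    rng = np.random.default_rng(seed)
    protected = np.zeros(n, dtype=bool)
    protected[rng.choice(n, size=n_protected, replace=False)] = True

    for var in variables:
        rate = rates.get(var, default_rate)
        drop = (~protected) & (rng.random(n) < rate)
        if records[var].dtype.kind in "if":
            records.loc[drop, var] = np.nan
        else:
            records[var] = records[var].astype(object)
            records.loc[drop, var] = None
    return records


def default_roster() -> list[VariableSpec]:
    """The default riverine variable roster of the study conditions.

    Eight candidate variables: four informative (water temperature, mean
    stream velocity, substrate type, presence of pools) and four pure-noise
    ones (water depth, river width, presence of algae, conductivity).
    """
    return [
        VariableSpec("temperature", CONTINUOUS, (2.0, 26.0), unit="degC", informative=True),
        VariableSpec("velocity", CONTINUOUS, (0.0, 2.0), unit="m/s", informative=True),
        VariableSpec("substrate", CATEGORICAL, ("fine", "gravel", "cobble", "boulder"),
                     informative=True),
        VariableSpec("pools", BINARY, ("0", "1"), informative=True),
        VariableSpec("depth", CONTINUOUS, (0.0, 3.0), unit="m"),
        VariableSpec("width", CONTINUOUS, (0.5, 20.0), unit="m"),
        VariableSpec("algae", BINARY, ("0", "1")),
        VariableSpec("conductivity", CONTINUOUS, (100.0, 1200.0), unit="uS/cm"),
    ]


def default_niche() -> TrueNiche:
    """The true niche paired with :func:`default_roster`.

    A cool-water, fast-flowing, coarse-substrate species with a preference
    for pool habitat; occurrence is deterministic at true HSI >= 0.6.
    """
    return TrueNiche(
        trapezoids={
            "temperature": (6.0, 10.0, 16.0, 20.0),
            "velocity": (0.2, 0.5, 1.0, 1.5),
        },
        class_si={
            "substrate": {"fine": 0.1, "gravel": 1.0, "cobble": 0.8, "boulder": 0.4},
            "pools": {"0": 0.3, "1": 1.0},
        },
        rule=THRESHOLD_RULE,
        threshold=0.6,
    )


def make_study_dataset(
    seed: int | None = None,
    n_presence: int = 166,
    n_background: int = 600,
    complete_fraction: float = 25 / 166,
    specs=None,
    niche: TrueNiche | None = None,
    spatial_extent=(0.0, 0.0, 10_000.0, 10_000.0),
    missing_rate: float = 0.5,
) -> tuple[pd.DataFrame, TrueNiche, list[VariableSpec]]:
    """A complete virtual-species dataset at the study's sample sizes.

    Generates environment + occurrence batches until the requested numbers
    of presence and background records are reached, then injects
    missingness so that roughly ``complete_fraction`` of the records stay
    fully observed (166 presences with ~25 complete by default). Returns
    ``(records, niche, specs)``.
    """
    specs = check_roster(specs if specs is not None else default_roster())
    niche = niche if niche is not None else default_niche()
    seeds = np.random.SeedSequence(seed).generate_state(4)

    chunks = []
    got_p = got_b = 0
    batch = max(1000, 4 * (n_presence + n_background))
    for attempt in range(50):
        env = generate_environment(batch, specs, spatial_extent,
                                   seed=int(seeds[0]) + attempt)
        lab = simulate_occurrence(env, niche, seed=int(seeds[1]) + attempt)
        chunks.append(lab)
        got_p += int((lab["status"] == PRESENCE).sum())
        got_b += int((lab["status"] == BACKGROUND).sum())
        if got_p >= n_presence and got_b >= n_background:
            break
    else:
        raise DataError(
            f"could not generate {n_presence} presences in 50 batches; "
            "the niche may be unreachable in this landscape"
        )

    pool = pd.concat(chunks, ignore_index=True)
    presences = pool[pool["status"] == PRESENCE].head(n_presence)
    backgrounds = pool[pool["status"] == BACKGROUND].head(n_background)

    # Missingness is injected per status stratum so the complete fraction is
    # exact within each (ceil(25/166 x 166) = 25 complete presences by
    # default) while staying label-independent inside a stratum.
    presences = inject_missingness(
        presences, complete_fraction=complete_fraction,
        seed=int(seeds[2]), default_rate=missing_rate,
    )
    backgrounds = inject_missingness(
        backgrounds, complete_fraction=complete_fraction,
        seed=int(seeds[3]), default_rate=missing_rate,
    )
    records = pd.concat([presences, backgrounds], ignore_index=True)
    records["site_id"] = [f"s{i:05d}" for i in range(len(records))]
    return records, niche, specs
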