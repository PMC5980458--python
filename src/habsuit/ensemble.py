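"""Model ensembles, support uncertainty, and scenario simulation.

Repeating the sample-then-optimise cycle with fresh balanced training
draws yields an ensemble of suitability models. The *support* of a
variable is the fraction of ensemble members whose selected model includes
its preference curve; the uncertainty on that selection is the binary
Shannon entropy of the inclusion indicator (normalised to [0, 1] by the
base-2 logarithm), which is maximal — exactly 1 — at 50% support.

For scenario simulation, a biotic and an abiotic monitoring table are
coupled spatially (nearest partner within a fixed radius, 100 m by
default), each site is collapsed to one scenario state per variable
(median; worst-case class on categorical ties), and every ensemble member
evaluates the scenario. Per site the ensemble yields a mean HSI, an HSI
standard deviation (the simulation uncertainty), and the minimum SI per
variable across members — the limiting-factor report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError
from .hpc import CategoricalHPC
from .hsi import SuitabilityModel
from .sampling import sample_training_set
from .selection import GAConfig, optimize_model
from .variables import RECORD_COLUMNS


def support_entropy(p):
    """Normalised binary Shannon entropy of an inclusion fraction.

    H(p) = -p log2 p - (1-p) log2 (1-p), with 0 log 0 = 0; H(0.5) = 1.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ConfigurationError("inclusion fraction must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(arr > 0, arr * np.log2(np.where(arr > 0, arr, 1.0)), 0.0) \
            - np.where(arr < 1, (1 - arr) * np.log2(np.where(arr < 1, 1 - arr, 1.0)), 0.0)
    h = np.maximum(h, 0.0)  # clip -0.0 and float round-off at the endpoints
    return h if h.shape else float(h)


@dataclass
class EnsembleModel:
    """A collection of independently optimised suitability models."""

    models: list
    seeds: list = field(default_factory=list)
    variables: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise DataError("an ensemble needs at least one model")
        if not self.variables:
            seen = []
            for m in self.models:
                for v in m.variables:
                    if v not in seen:
                        seen.append(v)
            self.variables = seen

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def support(self) -> dict:
        """Variable -> fraction of members including its curve."""
        return {
            v: sum(v in m.variables for m in self.models) / self.n_models
            for v in self.variables
        }

    @property
    def entropy(self) -> dict:
        """Variable -> selection uncertainty (binary Shannon entropy)."""
        return {v: support_entropy(p) for v, p in self.support.items()}

    def support_table(self) -> pd.DataFrame:
        sup = self.support
        ent = self.entropy
        return pd.DataFrame({
            "variable": list(sup),
            "support_pct": [100.0 * sup[v] for v in sup],
            "entropy": [ent[v] for v in sup],
        })

    def save(self, directory) -> None:
        """Serialise as a directory of member JSONs plus ``support.csv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"n_models": self.n_models, "variables": list(self.variables),
                "seeds": [int(s) for s in self.seeds] if self.seeds else []}
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=1))
        for i, m in enumerate(self.models):
            (directory / f"member_{i:04d}.json").write_text(json.dumps(m.to_dict()))
        self.support_table().to_csv(directory / "support.csv", index=False)

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        models = [
            SuitabilityModel.from_dict(json.loads(p.read_text()))
            for p in sorted(directory.glob("member_*.json"))
        ]
        return cls(models=models, seeds=meta.get("seeds", []),
                   variables=meta.get("variables", []))


def build_ensemble(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    hpcs,
    n_models: int = 200,
    ga_config: GAConfig | None = None,
    master_seed: int | None = None,
    n_each: int = 25,
    decay_scale: float | None = None,
    grid_step: float = 0.01,
    max_retries: int = 3,
) -> EnsembleModel:
    """Build an ensemble of independently trained suitability models.

    For each member a child seed is split off the master seed, a balanced
    training set is bootstrap sampled (uniform presences, distance-weighted
    backgrounds), and the GA selects the member's variables and threshold.
    A member whose training draw fails (for example a degenerate sample) is
    logged and re-drawn with a fresh child seed, up to ``max_retries``
    times. Identical master seeds reproduce the ensemble exactly.
    """
    if n_models < 1:
        raise ConfigurationError("n_models must be >= 1")
    ga_config = ga_config if ga_config is not None else GAConfig()
    # splittable child streams: one spawn per member attempt
    root = np.random.SeedSequence(master_seed)
    children = iter(root.spawn(n_models * (max_retries + 1)))

    models, seeds = [], []
    for i in range(n_models):
        last_error = None
        for _attempt in range(max_retries + 1):
            child = next(children)
            s_sample, s_ga = child.generate_state(2) >> 1  # keep below 2**31
            try:
                ts = sample_training_set(presences, backgrounds, n_each=n_each,
                                         decay_scale=decay_scale, seed=int(s_sample))
                member_cfg = GAConfig(**{**ga_config.__dict__, "seed": int(s_ga)})
                result = optimize_model(hpcs, ts, member_cfg, grid_step)
                models.append(result.model)
                seeds.append(int(s_sample))
                last_error = None
                break
            except DataError as exc:  # re-draw this member
                last_error = exc
                warnings.warn(f"ensemble member {i} failed ({exc}); re-drawing",
                              stacklevel=2)
        if last_error is not None:
            raise DataError(f"ensemble member {i} failed after {max_retries} retries: "
                            f"{last_error}")
    variables = [h.variable for h in hpcs]
    return EnsembleModel(models=models, seeds=seeds, variables=variables)


def couple_datasets(
    biotic_records: pd.DataFrame,
    abiotic_records: pd.DataFrame,
    max_distance_m: float = 100.0,
) -> pd.DataFrame:
    """Spatially join two monitoring tables (abiotic table as the base).

    Each abiotic record is paired with the nearest biotic record within
    ``max_distance_m`` (Euclidean, planar metres; a pair at exactly the
    radius is kept). Abiotic records with no partner in range are excluded;
    records without coordinates are skipped with a warning. The result
    keeps the base record's identity and variables and adds the partner's
    variables (only where the base lacks them), the partner id and the
    pairing distance.
    """
    if max_distance_m < 0:
        raise ConfigurationError("max_distance_m must be non-negative")

    def _valid_coords(df: pd.DataFrame, name: str) -> pd.DataFrame:
        ok = df[["x", "y"]].notna().all(axis=1)
        n_bad = int((~ok).sum())
        if n_bad:
            warnings.warn(f"{n_bad} {name} record(s) without coordinates skipped",
                          stacklevel=3)
        return df[ok]

    base = _valid_coords(abiotic_records, "abiotic")
    partner = _valid_coords(biotic_records, "biotic")
    if base.empty or partner.empty:
        return base.iloc[0:0].copy()

    tree = cKDTree(partner[["x", "y"]].to_numpy(dtype=float))
    dist, idx = tree.query(base[["x", "y"]].to_numpy(dtype=float), k=1)
    within = dist <= max_distance_m

    coupled = base[within].copy()
    matched = partner.iloc[idx[within]]
    partner_vars = [c for c in matched.columns
                    if c not in RECORD_COLUMNS and c not in coupled.columns]
    for col in partner_vars:
        coupled[col] = matched[col].to_numpy()
    coupled["partner_site_id"] = matched["site_id"].to_numpy() \
        if "site_id" in matched else matched.index.to_numpy()
    coupled["pair_distance_m"] = dist[within]
    return coupled


def aggregate_scenario(
    site_records: pd.DataFrame,
    specs,
    hpcs=None,
) -> pd.Series:
    """Collapse one site's records to a single scenario state per variable.

    Continuous variables take the median of their observations. For
    categorical/binary variables the median of the class codes (positions
    in the declared class order) is taken; when it falls between two
    classes the worst case wins — the tied class with the lower fitted SI
    (consulting ``hpcs`` when given), falling back to the later class in
    the declared order. Variables never observed at the site stay missing.
    """
    if site_records.empty:
        raise DataError("need at least one record per site")
    hpc_by_var = {h.variable: h for h in (hpcs or [])}
    out = {}
    for spec in specs:
        if spec.name not in site_records.columns:
            out[spec.name] = np.nan
            continue
        values = site_records[spec.name].dropna()
        if values.empty:
            out[spec.name] = np.nan
            continue
        if spec.is_continuous:
            out[spec.name] = float(np.median(values.astype(float)))
            continue
        classes = list(spec.classes)
        codes = np.sort([classes.index(str(v)) for v in values])
        med = float(np.median(codes))
        if med.is_integer():
            out[spec.name] = classes[int(med)]
        else:
            lo, hi = classes[int(np.floor(med))], classes[int(np.ceil(med))]
            hpc = hpc_by_var.get(spec.name)
            if isinstance(hpc, CategoricalHPC):
                si_lo = hpc.si_by_class.get(lo, 0.0)
                si_hi = hpc.si_by_class.get(hi, 0.0)
                if si_lo < si_hi:
                    out[spec.name] = lo
                elif si_hi < si_lo:
                    out[spec.name] = hi
                else:
                    out[spec.name] = hi  # SI tie: later class in declared order
            else:
                out[spec.name] = hi
        continue
    return pd.Series(out)


def build_scenario(
    coupled: pd.DataFrame,
    specs,
    hpcs=None,
    site_column: str = "site_id",
) -> pd.DataFrame:
    """One scenario row per site from a coupled record table."""
    rows = []
    for site_id, group in coupled.groupby(site_column, sort=False):
        row = aggregate_scenario(group, specs, hpcs)
        row[site_column] = site_id
        row["x"] = float(group["x"].iloc[0])
        row["y"] = float(group["y"].iloc[0])
        rows.append(row)
    if not rows:
        raise DataError("no sites to aggregate")
    frame = pd.DataFrame(rows)
    lead = [site_column, "x", "y"]
    return frame[lead + [c for c in frame.columns if c not in lead]]


@dataclass
class SiteSimulation:
    """Ensemble result at one site (one row of the simulation table)."""

    site_id: object
    x: float
    y: float
    mean_hsi: float
    sd_hsi: float
    min_si_by_variable: dict
    n_members_used: int


def simulate_ensemble(ensemble: EnsembleModel, scenario: pd.DataFrame) -> pd.DataFrame:
    """Run every ensemble member over the scenario sites.

    Per site: mean and standard deviation of the HSI across the members
    able to evaluate it (members with no observed variable at a site are
    excluded from that site's statistics, with the used count reported),
    plus the minimum SI per variable over members that include the
    variable and have input data — blank otherwise. Sites no member can
    evaluate are reported with NaN statistics.
    """
    n_sites = len(scenario)
    hsi_stack = np.full((ensemble.n_models, n_sites), np.nan)
    min_si = {v: np.full(n_sites, np.nan) for v in ensemble.variables}

    for k, model in enumerate(ensemble.models):
        si = model.si_table(scenario)
        from .hsi import _aggregate_si_frame
        hsi, m_used = _aggregate_si_frame(si)
        hsi_stack[k] = hsi
        for v in model.variables:
            col = si[v].to_numpy(dtype=float)
            cur = min_si[v]
            take = ~np.isnan(col) & (np.isnan(cur) | (col < cur))
            cur[take] = col[take]

    evaluable = ~np.isnan(hsi_stack)
    n_used = evaluable.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_hsi = np.nanmean(hsi_stack, axis=0)
        sd_hsi = np.nanstd(hsi_stack, axis=0)
    mean_hsi[n_used == 0] = np.nan
    sd_hsi[n_used == 0] = np.nan
    n_unsimulated = int((n_used == 0).sum())
    if n_unsimulated:
        warnings.warn(f"{n_unsimulated} site(s) evaluable by no ensemble member",
                      stacklevel=2)

    out = pd.DataFrame({
        "point": scenario["site_id"].to_numpy() if "site_id" in scenario
        else scenario.index.to_numpy(),
        "x": scenario["x"].to_numpy() if "x" in scenario else np.nan,
        "y": scenario["y"].to_numpy() if "y" in scenario else np.nan,
        "mean_hsi": mean_hsi,
        "sd_hsi": sd_hsi,
        "n_members_used": n_used,
    })
    for v in ensemble.variables:
        out[f"min_si_{v}"] = min_si[v]
    return out


def count_suitable(simulations: pd.DataFrame,
                   thresholds=(0.2, 0.6, 0.8)) -> dict:
    """Sites with mean HSI at/above vs below each threshold.

    Returns ``{threshold: (n_above, n_below)}``; unsimulated sites (NaN
    mean HSI) count in neither bin.
    """
    if simulations.empty:
        raise DataError("no simulations to count")
    mean_hsi = simulations["mean_hsi"].to_numpy(dtype=float)
    valid = mean_hsi[~np.isnan(mean_hsi)]
    return {
        float(t): (int((valid >= t).sum()), int((valid < t).sum()))
        for t in thresholds
    }
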