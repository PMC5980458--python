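"""Readers and writers for the canonical record CSV and run configuration.

One flat CSV format carries both biotic and abiotic tables, distinguished
by the ``status`` column: ``site_id, x, y, date, status, <variable...>``.
The missing-value token is an empty field. Dates are ISO-8601. Run
configurations (YAML or JSON) are validated into a :class:`RunConfig`
whose defaults are the study's settings: 200 curve bootstraps, 200
ensemble members, a 0.01 threshold grid and a 100 m coupling radius.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError, SchemaError
from .variables import BACKGROUND, PRESENCE, RECORD_COLUMNS, VariableSpec, check_roster

log = logging.getLogger("habsuit")


def write_records(records: pd.DataFrame, path, specs=None) -> None:
    """Write the canonical record CSV (empty field = missing)."""
    records = records.copy()
    if "date" in records.columns:
        records["date"] = pd.to_datetime(records["date"]).dt.strftime("%Y-%m-%d")
    lead = [c for c in RECORD_COLUMNS if c in records.columns]
    variable_cols = (
        [s.name for s in specs] if specs is not None
        else [c for c in records.columns if c not in RECORD_COLUMNS]
    )
    records[lead + variable_cols].to_csv(path, index=False)


def read_records(path, specs) -> pd.DataFrame:
    """Read and type-check a record CSV against a variable roster.

    Empty fields become missing values. Rows with an unparseable numeric
    value or an undeclared class are skipped with a logged line number;
    an undeclared column in the header is a schema error.
    """
    specs = check_roster(specs)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    declared = set(RECORD_COLUMNS) | {s.name for s in specs}
    unknown = [c for c in raw.columns if c not in declared]
    if unknown:
        raise SchemaError(f"unknown column(s) in {path}: {unknown}")
    missing_vars = [s.name for s in specs if s.name not in raw.columns]
    if missing_vars:
        raise SchemaError(f"roster variable(s) absent from {path}: {missing_vars}")

    bad_rows: set[int] = set()
    out = pd.DataFrame(index=raw.index)
    for col in RECORD_COLUMNS:
        if col not in raw.columns:
            continue
        if col in ("x", "y"):
            parsed = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
            bad = parsed.isna() & (raw[col] != "")
            _log_bad(bad, col, bad_rows)
            out[col] = parsed
        elif col == "date":
            parsed = pd.to_datetime(raw[col].replace("", pd.NaT), errors="coerce")
            bad = parsed.isna() & (raw[col] != "")
            _log_bad(bad, col, bad_rows)
            out[col] = parsed
        elif col == "status":
            ok = raw[col].isin([PRESENCE, BACKGROUND, ""])
            _log_bad(~ok, col, bad_rows)
            out[col] = raw[col].replace("", None)
        else:
            out[col] = raw[col]

    for spec in specs:
        col = raw[spec.name]
        if spec.is_continuous:
            parsed = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            bad = parsed.isna() & (col != "")
            _log_bad(bad, spec.name, bad_rows)
            out[spec.name] = parsed
        else:
            ok = col.isin(list(spec.classes) + [""])
            _log_bad(~ok, spec.name, bad_rows)
            out[spec.name] = col.replace("", None).astype(object)

    if bad_rows:
        out = out.drop(index=sorted(bad_rows))
    return out.reset_index(drop=True)


def _log_bad(bad_mask, column: str, bad_rows: set) -> None:
    for i in np.flatnonzero(np.asarray(bad_mask)):
        # +2: header line plus 1-based numbering
        log.warning("row %d: malformed value in column %r; row skipped", i + 2, column)
        bad_rows.add(int(i))


class GASettings(BaseModel):
    population_size: int = Field(50, ge=1)
    n_generations: int = Field(100, ge=1)
    crossover_rate: float = Field(0.7, ge=0.0, le=1.0)
    mutation_rate: float | None = Field(None, ge=0.0, le=1.0)
    tournament_size: int = Field(3, ge=1)
    elitism_count: int = Field(1, ge=0)
    stagnation_patience: int = Field(25, ge=1)


class VariableDecl(BaseModel):
    name: str
    kind: str
    support: list = []
    unit: str = ""
    informative: bool = False

    def to_spec(self) -> VariableSpec:
        return VariableSpec(name=self.name, kind=self.kind,
                            support=tuple(self.support), unit=self.unit,
                            informative=self.informative)


class RunConfig(BaseModel):
    """Validated run configuration with the study defaults filled in."""

    records: str | None = None
    abiotic_records: str | None = None
    output_dir: str = "habsuit_output"
    variables: list[VariableDecl] = []
    seed: int = 0
    n_boot: int = Field(200, ge=1)
    n_models: int = Field(200, ge=1)
    n_each: int = Field(25, ge=1)
    decay_scale: float | None = Field(None, gt=0.0)
    grid_step: float = Field(0.01, gt=0.0, le=1.0)
    coupling_radius_m: float = Field(100.0, ge=0.0)
    report_thresholds: list[float] = [0.2, 0.6, 0.8]
    ga: GASettings = GASettings()

    @field_validator("report_thresholds")
    @classmethod
    def _thresholds_in_unit(cls, v):
        if any(not 0.0 <= t <= 1.0 for t in v):
            raise ValueError("report thresholds must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _unique_variables(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("every variable must be declared exactly once")
        return self

    def specs(self) -> list[VariableSpec]:
        return [v.to_spec() for v in self.variables]


def validate_config(raw) -> RunConfig:
    """Validate a raw mapping (or YAML/JSON path) into a :class:`RunConfig`.

    All violations are aggregated into one report; defaults are logged so
    a run is replayable from its config alone.
    """
    if isinstance(raw, (str, Path)):
        raw = load_config_file(raw)
    try:
        cfg = RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigurationError(
            "invalid run configuration:\n  " + "\n  ".join(lines)
        ) from exc
    provided = set((raw or {}).keys())
    for name in type(cfg).model_fields:
        if name not in provided:
            log.info("config default applied: %s = %r", name, getattr(cfg, name))
    try:
        cfg.specs()
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid run configuration: {exc}") from exc
    return cfg


def load_config_file(path) -> dict:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(path.read_text()) or {}
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    raise ConfigurationError(f"unsupported config format: {path.suffix!r}")


def write_simulation(simulations: pd.DataFrame, path) -> None:
    """Write the per-site simulation table (blank = no input data)."""
    simulations.to_csv(path, index=False)


def write_metrics(reports, path) -> None:
    """Write one evaluation row per model."""
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
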