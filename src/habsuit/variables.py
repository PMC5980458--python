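"""Variable roster: declarations of the environmental variables a dataset carries.

A :class:`VariableSpec` declares one environmental variable — its name, its
measurement kind (continuous, categorical or binary), its unit and its
support (a numeric range for continuous variables, a class list otherwise).
The ``informative`` flag is only meaningful for synthetic data, where it marks
the variables that actually shape the simulated species' niche.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BINARY = "binary"
_KINDS = (CONTINUOUS, CATEGORICAL, BINARY)

#: Reserved columns of the canonical record table; variable columns follow.
RECORD_COLUMNS = ("site_id", "x", "y", "date", "status")

#: Occurrence status labels. Background sites are locations where the species
#: was never recorded present — they are not confirmed absences.
PRESENCE = "presence"
BACKGROUND = "background"


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one environmental variable.

    Parameters
    ----------
    name:
        Column name in the record table.
    kind:
        ``"continuous"``, ``"categorical"`` or ``"binary"``.
    support:
        ``(low, high)`` for continuous variables (finite, ``low < high``);
        a non-empty sequence of unique class labels otherwise. Binary
        variables default to the classes ``("0", "1")``.
    unit:
        Free-text measurement unit (metres, °C, ...); informational only.
    informative:
        Whether the variable drives the true niche of a synthetic species.
    """

    name: str
    kind: str
    support: tuple = field(default=())
    unit: str = ""
    informative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"variable {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if not self.name or self.name in RECORD_COLUMNS:
            raise ConfigurationError(f"invalid variable name {self.name!r}")
        if self.kind == CONTINUOUS:
            support = tuple(float(v) for v in self.support)
            if len(support) != 2:
                raise ConfigurationError(
                    f"variable {self.name!r}: continuous support must be (low, high)"
                )
            low, high = support
            if not (low < high) or not (abs(low) < float("inf") and abs(high) < float("inf")):
                raise ConfigurationError(
                    f"variable {self.name!r}: continuous support must be finite with low < high"
                )
        else:
            support = tuple(str(c) for c in self.support)
            if self.kind == BINARY and not support:
                support = ("0", "1")
            if not support:
                raise ConfigurationError(
                    f"variable {self.name!r}: class list must be non-empty"
                )
            if len(set(support)) != len(support):
                raise ConfigurationError(
                    f"variable {self.name!r}: class list must be unique"
                )
        object.__setattr__(self, "support", support)

    @property
    def is_continuous(self) -> bool:
        return self.kind == CONTINUOUS

    @property
    def classes(self) -> tuple:
        if self.is_continuous:
            raise ConfigurationError(f"variable {self.name!r} is continuous; no classes")
        return self.support

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "support": list(self.support),
            "unit": self.unit,
            "informative": self.informative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            support=tuple(d.get("support", ())),
            unit=d.get("unit", ""),
            informative=bool(d.get("informative", False)),
        )


def check_roster(specs: Sequence[VariableSpec]) -> list[VariableSpec]:
    """Validate a variable roster: non-empty, no duplicate names."""
    specs = list(specs)
    if not specs:
        raise ConfigurationError("variable roster is empty")
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate variable declaration: {sorted(dupes)}")
    return specs
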