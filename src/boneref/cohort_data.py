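"""Cohort data model and CSV I/O for multi-stack HRpQCT reference analysis.

One row of the cohort table is one measurement event: a participant, their
sex, age and anatomical site, a repeat-scan index (0 = baseline, >=1 =
same-day repeat for precision assessment) and a map of measured parameters
in canonical units (densities in gHA/cm^3, lengths in mm, areas in mm^2,
yield force in kN, ratios dimensionless).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Sex",
    "Site",
    "AgeGroup",
    "ParameterDef",
    "ParticipantRecord",
    "StratumKey",
    "SchemaError",
    "RowValidationError",
    "DEFAULT_PARAMETERS",
    "AGE_THRESHOLD",
    "read_cohort",
    "write_cohort",
    "stratify",
]

#: Plateau/decline breakpoint in years.  Lowered from the conventional 40 yr
#: because the reference cohort contains no participants aged 38-40.
AGE_THRESHOLD = 37.0

REQUIRED_COLUMNS = ("participant_id", "sex", "age", "site", "repeat_index")


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Site(str, enum.Enum):
    RADIUS = "radius"
    TIBIA = "tibia"


class AgeGroup(str, enum.Enum):
    """Young plateau group (age <= threshold) vs older declining group."""

    YOUNG = "G_le37"
    OLD = "G_gt37"


class SchemaError(ValueError):
    """The cohort table is missing required structure (columns, header)."""


class RowValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one measured parameter and its canonical unit."""

    name: str
    units: str
    kind: str  # densitometric | geometric | microstructural | mechanical
    extensivity: str  # intensive | extensive

    def __post_init__(self) -> None:
        if self.kind not in ("densitometric", "geometric", "microstructural", "mechanical"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.extensivity not in ("intensive", "extensive"):
            raise ValueError(f"unknown extensivity {self.extensivity!r}")


#: Canonical parameter schema.  Ratio-valued parameters (dimensionless, in
#: [0, 1]) are Tb.BV/TV, Ct.Po and Rel.Ct.Th; densities must be positive.
DEFAULT_PARAMETERS: tuple[ParameterDef, ...] = (
    ParameterDef("Tot.vBMD", "gHA/cm^3", "densitometric", "intensive"),
    ParameterDef("Ct.vBMD", "gHA/cm^3", "densitometric", "intensive"),
    ParameterDef("Tb.vBMD", "gHA/cm^3", "densitometric", "intensive"),
    ParameterDef("Tb.BV/TV", "-", "microstructural", "intensive"),
    ParameterDef("Ct.Th", "mm", "geometric", "extensive"),
    ParameterDef("Rel.Ct.Th", "-", "geometric", "intensive"),
    ParameterDef("Ct.Po", "-", "microstructural", "intensive"),
    ParameterDef("Tb.N", "1/mm", "microstructural", "intensive"),
    ParameterDef("Tb.Sp", "mm", "microstructural", "intensive"),
    ParameterDef("Tb.Th", "mm", "microstructural", "intensive"),
    ParameterDef("Tb.DA", "-", "microstructural", "intensive"),
    ParameterDef("Tot.Ar", "mm^2", "geometric", "extensive"),
    ParameterDef("F_y", "kN", "mechanical", "extensive"),
    ParameterDef("app_sigma_y", "MPa", "mechanical", "intensive"),
    ParameterDef("FN_aBMD", "g/cm^2", "densitometric", "intensive"),
)

_DENSITY_PARAMS = frozenset(
    {"Tot.vBMD", "Ct.vBMD", "Tb.vBMD", "FN_aBMD"}
)
_RATIO_PARAMS = frozenset({"Tb.BV/TV", "Ct.Po", "Rel.Ct.Th"})


@dataclass
class ParticipantRecord:
    """One measurement event of one participant at one site."""

    participant_id: str
    sex: Sex
    age: float
    site: Site
    repeat_index: int = 0
    measurements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.site = Site(self.site)
        self.age = float(self.age)
        self.repeat_index = int(self.repeat_index)
        if not 18.0 <= self.age <= 110.0:
            raise ValueError(f"age {self.age} outside [18, 110]")
        if self.repeat_index < 0:
            raise ValueError("repeat_index must be >= 0")
        for name, value in self.measurements.items():
            _validate_measurement(name, value)

    @property
    def age_group(self) -> AgeGroup:
        return AgeGroup.YOUNG if self.age <= AGE_THRESHOLD else AgeGroup.OLD

    def get(self, parameter: str) -> float | None:
        return self.measurements.get(parameter)


def _validate_measurement(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} = {value!r} is not finite")
    if name in _DENSITY_PARAMS and value <= 0:
        raise ValueError(f"density {name} = {value} must be > 0")
    if name in _RATIO_PARAMS and not 0.0 <= value <= 1.0:
        raise ValueError(f"ratio {name} = {value} outside [0, 1]")


@dataclass(frozen=True)
class StratumKey:
    """Stratification key: sex x site x age group (threshold 37 yr)."""

    sex: Sex
    site: Site
    age_group: AgeGroup

    @classmethod
    def for_record(cls, record: ParticipantRecord, threshold: float = AGE_THRESHOLD) -> "StratumKey":
        group = AgeGroup.YOUNG if record.age <= threshold else AgeGroup.OLD
        return cls(record.sex, record.site, group)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | Path,
    schema: Iterable[ParameterDef] | None = None,
) -> list[ParticipantRecord]:
    """Read a cohort CSV into validated :class:`ParticipantRecord` objects.

    The table must carry the required columns ``participant_id, sex, age,
    site, repeat_index``; every other column is treated as a parameter.
    Empty cells mean the parameter was not measured for that participant.
    Row numbers in error messages are 1-based data rows (the header is row 0).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    param_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    records: list[ParticipantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowmap = dict(zip(df.columns, row))
        measurements: dict[str, float] = {}
        for col in param_cols:
            cell = rowmap[col].strip()
            if cell == "":
                continue
            try:
                measurements[col] = float(cell)
            except ValueError:
                raise RowValidationError(i, f"non-numeric value {cell!r} for {col}") from None
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(rowmap["participant_id"]),
                    sex=rowmap["sex"],
                    age=float(rowmap["age"]),
                    site=rowmap["site"],
                    repeat_index=int(rowmap["repeat_index"]),
                    measurements=measurements,
                )
            )
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
    return records


def write_cohort(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    """Write records to CSV, one column per parameter seen in any record."""
    records = list(records)
    param_cols: list[str] = []
    for r in records:
        for name in r.measurements:
            if name not in param_cols:
                param_cols.append(name)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "sex": r.sex.value,
            "age": repr(r.age),
            "site": r.site.value,
            "repeat_index": r.repeat_index,
        }
        for name in param_cols:
            v = r.measurements.get(name)
            row[name] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + param_cols).to_csv(path, index=False)


def read_parameter_schema(path: str | Path) -> list[ParameterDef]:
    """Load a parameter schema from a JSON list of ParameterDef fields."""
    with open(path) as fh:
        entries = json.load(fh)
    return [ParameterDef(**e) for e in entries]


def write_parameter_schema(schema: Iterable[ParameterDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([vars(p) for p in schema], fh, indent=1)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def stratify(
    records: Iterable[ParticipantRecord],
    threshold: float = AGE_THRESHOLD,
) -> dict[StratumKey, list[ParticipantRecord]]:
    """Partition baseline records by sex, site and age group.

    Only baseline scans (``repeat_index == 0``) enter the strata; same-day
    repeats exist solely for precision-error estimation and must not inflate
    the reference fits.  A participant aged exactly at the threshold belongs
    to the young group.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out: dict[StratumKey, list[ParticipantRecord]] = {}
    for r in records:
        if r.repeat_index != 0:
            continue
        out.setdefault(StratumKey.for_record(r, threshold), []).append(r)
    return out


def baseline_values(
    records: Iterable[ParticipantRecord], parameter: str
) -> list[tuple[float, float]]:
    """(age, value) pairs for baseline records carrying ``parameter``."""
    return [
        (r.age, r.measurements[parameter])
        for r in records
        if r.repeat_index == 0 and parameter in r.measurements
    ]
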