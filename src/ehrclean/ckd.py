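"""Clinical Knowledge Database (CKD): the rule table that drives cleaning.

The CKD is a small curated table holding, per clinical variable, the set of
units the variable may legitimately be reported in, the multiplicative rate
converting each unit into the variable's standard unit, the normal range
(reference interval for healthy individuals) and the extreme range
(biologically plausible interval). Both ranges are expressed in the standard
unit. Every cleaning stage — fuzzy unit repair, unit conversion, magnitude
correction and outlier removal — queries this table; the pipeline itself
contains no variable-specific constants.

Here "CKD" always means this knowledge database, never chronic kidney
disease.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "UnitEntry",
    "ValueRange",
    "VariableSpec",
    "CKDTable",
    "CKDError",
    "CKD_CSV_COLUMNS",
    "load_ckd",
    "save_ckd",
    "get_spec",
    "rate_to_standard",
    "normalize_unit",
]

#: Canonical CSV column layout: one row per (variable, unit); the range and
#: standard-unit cells need only be populated on the first row of a variable
#: group (blank thereafter).
CKD_CSV_COLUMNS = [
    "variable_code",
    "variable_name",
    "unit_label",
    "rate_to_standard",
    "standard_unit",
    "normal_min",
    "normal_max",
    "extreme_min",
    "extreme_max",
]

_WS = re.compile(r"\s+")


class CKDError(ValueError):
    """Raised when a CKD file fails to parse or validate."""


def normalize_unit(label: str) -> str:
    """Trim and collapse internal whitespace of a unit label.

    Casing is preserved for display; comparisons casefold separately
    (clinical sources print the same unit as e.g. ``Mg/dL`` and ``mg/dL``).
    """
    return _WS.sub(" ", str(label).strip())


@dataclass(frozen=True)
class UnitEntry:
    """One legitimate unit for a variable and its conversion rate.

    ``rate_to_standard`` is the multiplicative factor taking a value
    expressed in ``unit_label`` into the variable's standard unit.
    """

    unit_label: str
    rate_to_standard: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_label", normalize_unit(self.unit_label))
        object.__setattr__(self, "rate_to_standard", float(self.rate_to_standard))
        if not self.unit_label:
            raise CKDError("unit_label is empty after normalization")
        if not math.isfinite(self.rate_to_standard) or self.rate_to_standard <= 0:
            raise CKDError(
                f"rate_to_standard must be a positive finite number, "
                f"got {self.rate_to_standard!r} for unit {self.unit_label!r}"
            )


@dataclass(frozen=True)
class ValueRange:
    """A closed numeric interval in the variable's standard unit."""

    min: float
    max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "min", float(self.min))
        object.__setattr__(self, "max", float(self.max))
        if not (self.min < self.max):
            raise CKDError(f"range min must be < max, got [{self.min}, {self.max}]")

    def contains(self, value: float) -> bool:
        """Inclusive membership test."""
        return self.min <= value <= self.max


# Tolerance for "the standard unit has rate 1"; rates are curated constants,
# so anything beyond float noise is a curation bug.
_RATE_ONE_TOL = 1e-12


@dataclass(frozen=True)
class VariableSpec:
    """All cleaning knowledge for one clinical variable.

    Invariants enforced at construction: exactly one unit carries rate 1
    (the standard unit itself), and the normal range is nested inside the
    extreme range.
    """

    variable_code: str
    variable_name: str
    standard_unit: str
    units: tuple[UnitEntry, ...]
    normal_range: ValueRange
    extreme_range: ValueRange

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_code", str(self.variable_code).strip())
        object.__setattr__(self, "standard_unit", normalize_unit(self.standard_unit))
        object.__setattr__(self, "units", tuple(self.units))
        code = self.variable_code
        if not code:
            raise CKDError("variable_code is empty")
        if not self.units:
            raise CKDError(f"{code}: no units defined")
        labels = [u.unit_label.casefold() for u in self.units]
        if len(set(labels)) != len(labels):
            raise CKDError(f"{code}: duplicate unit labels in spec")
        std = self.standard_unit.casefold()
        std_entries = [u for u in self.units if u.unit_label.casefold() == std]
        if not std_entries:
            raise CKDError(f"{code}: missing standard-unit row for {self.standard_unit!r}")
        if abs(std_entries[0].rate_to_standard - 1.0) > _RATE_ONE_TOL:
            raise CKDError(
                f"{code}: standard unit {self.standard_unit!r} has rate "
                f"{std_entries[0].rate_to_standard}, expected 1"
            )
        ones = [u for u in self.units if abs(u.rate_to_standard - 1.0) <= _RATE_ONE_TOL]
        if len(ones) != 1:
            raise CKDError(
                f"{code}: expected exactly one unit with rate 1, found "
                f"{[u.unit_label for u in ones]}"
            )
        if not (
            self.extreme_range.min <= self.normal_range.min
            and self.normal_range.max <= self.extreme_range.max
        ):
            raise CKDError(f"{code}: normal range must lie within extreme range")

    @property
    def unit_labels(self) -> list[str]:
        """Unit labels in CKD order, standard unit first."""
        std = self.standard_unit.casefold()
        labels = [u.unit_label for u in self.units]
        labels.sort(key=lambda lab: 0 if lab.casefold() == std else 1)
        return labels

    def rate_for(self, unit_label: str) -> float:
        """Conversion rate into the standard unit for ``unit_label``.

        The lookup is case-insensitive on normalized labels; the standard
        unit returns exactly 1.0.
        """
        wanted = normalize_unit(unit_label).casefold()
        if wanted == self.standard_unit.casefold():
            return 1.0
        for u in self.units:
            if u.unit_label.casefold() == wanted:
                return u.rate_to_standard
        raise CKDError(
            f"{self.variable_code}: unit {unit_label!r} not among "
            f"{[u.unit_label for u in self.units]}"
        )


@dataclass(frozen=True)
class CKDTable:
    """A validated set of variable specs keyed by variable code."""

    specs: Mapping[str, VariableSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.specs:
            raise CKDError("no variables in CKD")

    def __iter__(self):
        return iter(self.specs.values())

    def __len__(self) -> int:
        return len(self.specs)

    def get(self, variable_code: str) -> VariableSpec:
        code = str(variable_code).strip()
        try:
            return self.specs[code]
        except KeyError:
            raise CKDError(
                f"unknown variable code {code!r}; known codes: "
                f"{sorted(self.specs)}"
            ) from None


def get_spec(ckd: CKDTable, variable_code: str) -> VariableSpec:
    """Exact lookup (after whitespace trimming) of one variable's spec."""
    return ckd.get(variable_code)


def rate_to_standard(spec: VariableSpec, unit_label: str) -> float:
    """Multiplicative conversion factor from ``unit_label`` into the standard unit."""
    return spec.rate_for(unit_label)


def _is_blank(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or str(x).strip() == ""


def _specs_from_rows(rows: pd.DataFrame) -> dict[str, VariableSpec]:
    specs: dict[str, VariableSpec] = {}
    problems: list[str] = []
    # Group rows by variable code, preserving file order; a code appearing
    # in two non-adjacent blocks is a curation bug, not a silent merge.
    rows = rows.reset_index(drop=True)
    codes = rows["variable_code"].astype(str).str.strip()
    order = codes[~codes.duplicated()].tolist()
    block_starts = (codes != codes.shift()).cumsum()
    for code in order:
        grp = rows[codes == code]
        if block_starts[grp.index].nunique() > 1:
            raise CKDError(f"variable code {code!r} appears in non-contiguous groups")
        first = grp.iloc[0]
        try:
            try:
                units = []
                for _, r in grp.iterrows():
                    if _is_blank(r["unit_label"]):
                        raise CKDError(f"{code}: blank unit_label")
                    units.append(UnitEntry(r["unit_label"], float(r["rate_to_standard"])))
                units = tuple(units)
            except (TypeError, ValueError) as exc:
                raise CKDError(f"{code}: bad unit row ({exc})") from None
            for col in ("standard_unit", "normal_min", "normal_max", "extreme_min", "extreme_max"):
                if _is_blank(first[col]):
                    raise CKDError(f"{code}: first row of group has blank {col!r}")
            name = "" if _is_blank(first["variable_name"]) else str(first["variable_name"]).strip()
            spec = VariableSpec(
                variable_code=code,
                variable_name=name,
                standard_unit=str(first["standard_unit"]),
                units=units,
                normal_range=ValueRange(float(first["normal_min"]), float(first["normal_max"])),
                extreme_range=ValueRange(float(first["extreme_min"]), float(first["extreme_max"])),
            )
        except CKDError as exc:
            problems.append(str(exc))
            continue
        specs[code] = spec
    if problems:
        raise CKDError("CKD validation failed: " + "; ".join(problems))
    return specs


def load_ckd(path: str | Path, dialect: str | None = None) -> CKDTable:
    """Load and validate a CKD from CSV or JSON.

    CSV uses one row per (variable, unit) with the :data:`CKD_CSV_COLUMNS`
    header; the standard unit and ranges are read from the first row of each
    variable group and may be blank on subsequent rows. JSON is a list of
    spec objects with explicit ``units`` arrays.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        try:
            rows = pd.read_csv(path, dtype=str, skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            raise CKDError(f"{path}: no variables (empty file)") from None
        missing = [c for c in CKD_CSV_COLUMNS if c not in rows.columns]
        if missing:
            raise CKDError(f"{path}: missing CKD columns {missing}")
        if rows.empty:
            raise CKDError(f"{path}: no variables")
        specs = _specs_from_rows(rows)
    elif dialect == "json":
        raw = json.loads(path.read_text())
        if isinstance(raw, dict):
            raw = raw.get("specs", [])
        if not raw:
            raise CKDError(f"{path}: no variables")
        specs = {}
        for obj in raw:
            spec = VariableSpec(
                variable_code=obj["variable_code"],
                variable_name=obj.get("variable_name", ""),
                standard_unit=obj["standard_unit"],
                units=tuple(
                    UnitEntry(u["unit_label"], u["rate_to_standard"]) for u in obj["units"]
                ),
                normal_range=ValueRange(**obj["normal_range"]),
                extreme_range=ValueRange(**obj["extreme_range"]),
            )
            if spec.variable_code in specs:
                raise CKDError(f"duplicate variable code {spec.variable_code!r}")
            specs[spec.variable_code] = spec
    else:
        raise CKDError(f"unknown CKD dialect {dialect!r}")
    return CKDTable(specs=specs, provenance=str(path))


def save_ckd(ckd: CKDTable, path: str | Path, dialect: str | None = None) -> None:
    """Serialize a CKD back to CSV (grouped-row layout) or JSON."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        records = []
        for spec in ckd:
            for i, u in enumerate(spec.units):
                records.append(
                    {
                        "variable_code": spec.variable_code,
                        "variable_name": spec.variable_name if i == 0 else "",
                        "unit_label": u.unit_label,
                        "rate_to_standard": repr(u.rate_to_standard),
                        "standard_unit": spec.standard_unit if i == 0 else "",
                        "normal_min": repr(spec.normal_range.min) if i == 0 else "",
                        "normal_max": repr(spec.normal_range.max) if i == 0 else "",
                        "extreme_min": repr(spec.extreme_range.min) if i == 0 else "",
                        "extreme_max": repr(spec.extreme_range.max) if i == 0 else "",
                    }
                )
        pd.DataFrame(records, columns=CKD_CSV_COLUMNS).to_csv(path, index=False)
    elif dialect == "json":
        out = [
            {
                "variable_code": s.variable_code,
                "variable_name": s.variable_name,
                "standard_unit": s.standard_unit,
                "units": [
                    {"unit_label": u.unit_label, "rate_to_standard": u.rate_to_standard}
                    for u in s.units
                ],
                "normal_range": {"min": s.normal_range.min, "max": s.normal_range.max},
                "extreme_range": {"min": s.extreme_range.min, "max": s.extreme_range.max},
            }
            for s in ckd
        ]
        path.write_text(json.dumps(out, indent=2))
    else:
        raise CKDError(f"unknown CKD dialect {dialect!r}")
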