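"""Synthetic dirty-record generator with labeled ground truth.

Real primary-care exports are restricted, so every stage of the pipeline is
exercised on generated tables that mimic the raw export layout (patient id,
GP id, test code, two value fields, a unit string) and carry the observed
error taxonomy under controlled probabilities: misspelled units, meaningless unit tokens, values
re-expressed in an alternate legitimate unit, power-of-ten magnitude
errors, biologically implausible values, and meaningless value tokens.

Each corrupted record receives exactly one error type, and a truth table
records the clean standard-unit value plus what was injected, so tests can
score recovery exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ckd import VariableSpec
from .preprocess import RAW_CSV_COLUMNS

__all__ = [
    "CorruptionConfig",
    "ERROR_TYPES",
    "generate_clean_records",
    "corrupt_records",
]

ERROR_TYPES = (
    "unit_typo",
    "unit_meaningless",
    "alternate_valid_unit",
    "magnitude_error",
    "implausible",
    "meaningless_value",
)

_MEANINGLESS_UNIT_TOKENS = ("??", "77", "1", "NULL")
_MEANINGLESS_VALUE_TOKENS = ("NULL", "na", "n", ",", "??")
_TYPO_ALPHABET = string.ascii_lowercase + "/%μ0123456789"


@dataclass
class CorruptionConfig:
    """Probabilities of each injected error; at most one error per record."""

    p_unit_typo: float = 0.0
    p_unit_meaningless: float = 0.0
    p_alternate_valid_unit: float = 0.0
    p_magnitude_error: float = 0.0
    p_implausible: float = 0.0
    p_meaningless_value: float = 0.0
    exponent_choices: tuple[int, ...] = (-2, -1, 1, 2)
    typo_edits: tuple[int, ...] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.probabilities
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("corruption probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-12:
            raise ValueError("corruption probabilities must sum to <= 1")
        if 0 in self.exponent_choices:
            raise ValueError("exponent_choices must exclude 0")

    @property
    def probabilities(self) -> list[float]:
        return [
            self.p_unit_typo,
            self.p_unit_meaningless,
            self.p_alternate_valid_unit,
            self.p_magnitude_error,
            self.p_implausible,
            self.p_meaningless_value,
        ]


def _format_value(v: float) -> str:
    """Render a value as the exports print them (dotted decimals, lossless)."""
    s = repr(float(v))
    return s if "e" not in s else f"{v:.1f}"


def generate_clean_records(spec: VariableSpec, n: int, seed: int) -> pd.DataFrame:
    """A raw-export-shaped table of ``n`` clean records for one variable.

    Values are sampled uniformly inside the normal range (range membership
    is all the pipeline inspects, and uniform sampling exercises the
    boundaries); units are the standard unit. Reproducible given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    values = rng.uniform(spec.normal_range.min, spec.normal_range.max, size=n)
    years = rng.integers(1994, 2016, size=n)
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{100000 + i}" for i in range(n)],
            "gp_id": [f"GP_{rng.integers(1, 112)}" for _ in range(n)],
            "birth_year": rng.integers(1920, 2010, size=n).astype(str),
            "sex": rng.choice(["F", "M"], size=n),
            "test_code": spec.variable_code,
            "date": [f"01/07/{y}" for y in years],
            "year": years.astype(str),
            "test_name": spec.variable_name,
            "num1": [_format_value(v) for v in values],
            "num2": "",
            "unit": spec.standard_unit,
        },
        columns=RAW_CSV_COLUMNS,
    )
    frame.attrs["true_values"] = values
    return frame


def _typo(
    unit: str,
    n_edits: int,
    rng: np.random.Generator,
    forbidden: frozenset[str] = frozenset(),
) -> str:
    """Apply ``n_edits`` random character edits (the matcher's own alphabet).

    A result that casefolds to any ``forbidden`` label (the variable's
    legitimate units) is rerolled: such a string is a different valid unit,
    not a typo, and would silently relabel the measurement.
    """
    for _ in range(20):
        s = list(unit)
        for _ in range(n_edits):
            op = rng.choice(["insert", "delete", "substitute"]) if len(s) > 1 else "insert"
            if op == "insert":
                pos = int(rng.integers(0, len(s) + 1))
                s.insert(pos, str(rng.choice(list(_TYPO_ALPHABET))))
            elif op == "delete":
                pos = int(rng.integers(0, len(s)))
                del s[pos]
            else:
                pos = int(rng.integers(0, len(s)))
                old = s[pos]
                choices = [c for c in _TYPO_ALPHABET if c != old.lower()]
                s[pos] = str(rng.choice(choices))
        result = "".join(s)
        if result and result.casefold() not in forbidden:
            return result
    return unit + str(rng.choice(list(_TYPO_ALPHABET)))


def _implausible_value(spec: VariableSpec, rng: np.random.Generator) -> float:
    """A value no power-of-ten shift (|k| <= 6) brings inside the extreme range."""
    hi = spec.extreme_range.max
    return hi * 10.0**7 * rng.uniform(1.5, 8.0)


def corrupt_records(
    records: pd.DataFrame,
    spec: VariableSpec,
    config: CorruptionConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject labeled errors into a clean table.

    Returns ``(dirty records, truth table)``. The truth table has one row
    per input record: ``record_id`` (row position), ``true_value`` (clean
    value in the standard unit), ``error_type`` ("" for untouched rows) and
    ``exponent`` (the injected power of ten, 0 otherwise). Exactly one
    corruption applies per selected record; with all probabilities zero the
    output equals the input.
    """
    rng = np.random.default_rng(config.seed)
    dirty = records.copy(deep=True)
    n = len(dirty)
    true_values = records.attrs.get("true_values")
    if true_values is None:
        true_values = pd.to_numeric(records["num1"], errors="coerce").to_numpy()
    probs = config.probabilities + [1.0 - sum(config.probabilities)]
    draws = rng.choice(len(ERROR_TYPES) + 1, size=n, p=probs)

    alt_units = [
        u for u in spec.units if u.unit_label.casefold() != spec.standard_unit.casefold()
    ]
    valid_labels = frozenset(u.unit_label.casefold() for u in spec.units)
    labels = []
    for i in range(n):
        kind = ERROR_TYPES[draws[i]] if draws[i] < len(ERROR_TYPES) else ""
        true = float(true_values[i])
        exponent = 0
        if kind == "alternate_valid_unit" and not alt_units:
            kind = ""  # spec has no alternate unit to express the value in
        if kind == "unit_typo":
            edits = int(rng.choice(config.typo_edits))
            dirty.iat[i, dirty.columns.get_loc("unit")] = _typo(
                spec.standard_unit, edits, rng, valid_labels
            )
        elif kind == "unit_meaningless":
            dirty.iat[i, dirty.columns.get_loc("unit")] = str(
                rng.choice(_MEANINGLESS_UNIT_TOKENS)
            )
        elif kind == "alternate_valid_unit":
            u = alt_units[int(rng.integers(0, len(alt_units)))]
            dirty.iat[i, dirty.columns.get_loc("num1")] = _format_value(
                true / u.rate_to_standard
            )
            dirty.iat[i, dirty.columns.get_loc("unit")] = u.unit_label
        elif kind == "magnitude_error":
            exponent = int(rng.choice(config.exponent_choices))
            dirty.iat[i, dirty.columns.get_loc("num1")] = _format_value(
                true * 10.0**exponent
            )
        elif kind == "implausible":
            dirty.iat[i, dirty.columns.get_loc("num1")] = _format_value(
                _implausible_value(spec, rng)
            )
        elif kind == "meaningless_value":
            dirty.iat[i, dirty.columns.get_loc("num1")] = str(
                rng.choice(_MEANINGLESS_VALUE_TOKENS)
            )
        labels.append(
            {
                "record_id": i,
                "true_value": true,
                "error_type": kind,
                "exponent": exponent,
            }
        )
    return dirty, pd.DataFrame(labels)
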