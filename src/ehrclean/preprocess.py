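"""First cleaning stage: turn untrusted value and unit tokens into usable data.

Raw registry exports carry free-text value cells ("56.50", " 1 650 ",
"NULL", ",") and unit cells that may be meaningless ("??", "77", "1").
This stage strips unexpected characters, resolves decimal/grouping
separator ambiguity (the source data mixes Belgian comma decimals with
dotted decimals), coerces to float, and maps meaningless tokens to missing.
No imputation ever happens: a value can only move from present to missing.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MissingReason",
    "Missing",
    "RawRecord",
    "DEFAULT_MEANINGLESS_TOKENS",
    "RAW_CSV_COLUMNS",
    "coerce_numeric",
    "clean_unit_token",
    "preprocess_records",
    "PreprocessCounters",
]


class MissingReason(str, enum.Enum):
    """Why a cell holds no usable value; closed enumeration, one per cell."""

    MEANINGLESS_TOKEN = "meaningless_token"
    UNPARSEABLE_NUMBER = "unparseable_number"
    UNMATCHED_UNIT = "unmatched_unit"
    OUTLIER = "outlier"
    ORIGINALLY_MISSING = "originally_missing"


@dataclass(frozen=True)
class Missing:
    """A missing value carrying its reason code."""

    reason: MissingReason

    def __bool__(self) -> bool:  # truthiness: a Missing is "no value"
        return False


#: Tokens treated as "no information" after casefolding. Seeded from the
#: error inventory observed in primary-care registry exports; extend per run.
DEFAULT_MEANINGLESS_TOKENS = frozenset(
    {"", ",", ".", "n", "null", "na", "nan", "?", "??", "-"}
)

#: Default raw-record CSV header (remappable in the run config).
RAW_CSV_COLUMNS = [
    "patient_id",
    "gp_id",
    "birth_year",
    "sex",
    "test_code",
    "date",
    "year",
    "test_name",
    "num1",
    "num2",
    "unit",
]


@dataclass
class RawRecord:
    """One measurement/lab row with untrusted value and unit tokens."""

    patient_id: str = ""
    gp_id: str = ""
    birth_year: str = ""
    sex: str = ""
    test_code: str = ""
    date: str = ""
    year: str = ""
    test_name: str = ""
    value_token: str = ""
    value2_token: str = ""
    unit_token: str = ""


_DIGIT = re.compile(r"\d")
_KEEP = re.compile(r"[^0-9.,+\-]")
_WS = re.compile(r"\s+")
_GROUPED_COMMAS = re.compile(r"^[+-]?\d{1,3}(,\d{3})+$")


def _parse_separators(token: str) -> float | None:
    """Resolve '.'/',' roles and parse; None when no unambiguous reading."""
    sign = 1.0
    if token and token[0] in "+-":
        sign = -1.0 if token[0] == "-" else 1.0
        body = token[1:]
    else:
        body = token
    if not body or "+" in body or "-" in body:
        return None
    dots, commas = body.count("."), body.count(",")
    if dots and commas:
        # The rightmost separator is the decimal mark, the other groups digits.
        dec = "." if body.rfind(".") > body.rfind(",") else ","
        grp = "," if dec == "." else "."
        if body.count(dec) > 1:
            return None
        body = body.replace(grp, "").replace(dec, ".")
    elif commas:
        if _GROUPED_COMMAS.match(("+" if sign > 0 else "-") + body) or _GROUPED_COMMAS.match(body):
            body = body.replace(",", "")  # "16,000" -> 16000
        elif commas == 1:
            body = body.replace(",", ".")  # lone comma is a decimal mark
        else:
            return None
    elif dots > 1:
        return None
    if not _DIGIT.search(body):
        return None
    try:
        value = sign * float(body)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def coerce_numeric(
    value_token: str | float | None,
    meaningless_tokens: frozenset[str] | set[str] = DEFAULT_MEANINGLESS_TOKENS,
) -> float | Missing:
    """Coerce one raw value cell to a float, or to :class:`Missing`.

    Total and deterministic: never raises. Tokens on the meaningless list or
    containing no digit become ``Missing(meaningless_token)``; tokens with
    digits but no unambiguous numeric reading become
    ``Missing(unparseable_number)``. Whitespace and characters outside
    ``[0-9 . , + -]`` are stripped before parsing, so `` 1 650 `` reads 1650.
    """
    if value_token is None:
        return Missing(MissingReason.ORIGINALLY_MISSING)
    if isinstance(value_token, float) and math.isnan(value_token):
        return Missing(MissingReason.ORIGINALLY_MISSING)
    if isinstance(value_token, (int, float)):
        v = float(value_token)
        return v if math.isfinite(v) else Missing(MissingReason.UNPARSEABLE_NUMBER)
    token = str(value_token).strip()
    if token == "":
        return Missing(MissingReason.ORIGINALLY_MISSING)
    if token.casefold() in meaningless_tokens:
        return Missing(MissingReason.MEANINGLESS_TOKEN)
    if not _DIGIT.search(token):
        return Missing(MissingReason.MEANINGLESS_TOKEN)
    stripped = _KEEP.sub("", _WS.sub("", token))
    value = _parse_separators(stripped)
    if value is None:
        return Missing(MissingReason.UNPARSEABLE_NUMBER)
    return value


def clean_unit_token(
    unit_token: str | float | None,
    meaningless_tokens: frozenset[str] | set[str] = DEFAULT_MEANINGLESS_TOKENS,
) -> str:
    """Normalize one raw unit cell; meaningless tokens collapse to ``""``.

    Empty, all-punctuation, all-digit, and listed tokens return the empty
    string; everything else is returned trimmed with internal whitespace
    collapsed.
    """
    if unit_token is None or (isinstance(unit_token, float) and math.isnan(unit_token)):
        return ""
    token = _WS.sub(" ", str(unit_token).strip())
    if not token or token.casefold() in meaningless_tokens:
        return ""
    if token.isdigit():
        return ""
    if not any(ch.isalnum() for ch in token):
        return ""
    return token


@dataclass
class PreprocessCounters:
    """Per-stage tallies of what preprocessing did to the value column(s)."""

    n_values: int = 0
    n_newly_missing: int = 0
    by_reason: dict = field(default_factory=dict)
    n_units_blanked: int = 0

    @property
    def newly_missing_pct(self) -> float:
        return 100.0 * self.n_newly_missing / self.n_values if self.n_values else 0.0


def preprocess_records(
    records: Sequence[RawRecord],
    meaningless_tokens: frozenset[str] | set[str] = DEFAULT_MEANINGLESS_TOKENS,
    include_value2: bool = False,
) -> tuple[list[dict], PreprocessCounters]:
    """Parse every record's value(s) and unit; count what went missing.

    Returns parsed records (dicts with ``value``, optional ``value2``,
    ``unit`` and the passthrough fields) plus counters. Missingness can only
    grow here — nothing is imputed.
    """
    out: list[dict] = []
    counters = PreprocessCounters()
    for rec in records:
        parsed: dict = {
            "record": rec,
            "unit": clean_unit_token(rec.unit_token, meaningless_tokens),
        }
        if parsed["unit"] == "" and str(rec.unit_token or "").strip() != "":
            counters.n_units_blanked += 1
        tokens = [("value", rec.value_token)]
        if include_value2:
            tokens.append(("value2", rec.value2_token))
        for key, token in tokens:
            value = coerce_numeric(token, meaningless_tokens)
            parsed[key] = value
            counters.n_values += 1
            if isinstance(value, Missing):
                if value.reason is not MissingReason.ORIGINALLY_MISSING:
                    counters.n_newly_missing += 1
                counters.by_reason[value.reason.value] = (
                    counters.by_reason.get(value.reason.value, 0) + 1
                )
        out.append(parsed)
    return out, counters
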