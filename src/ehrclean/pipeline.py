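"""End-to-end cleaning pipeline: extract → preprocess → unit repair →
conversion → range cleaning → quality report.

The pipeline operates per clinical variable. Records with the variable's
test code are extracted from the raw table; value and unit tokens are
parsed; unit tokens are fuzzy-matched against the variable's legitimate
units; values are converted into the standard unit; magnitude errors are
repaired and outliers removed; snapshots taken after each stage feed a
:class:`~ehrclean.qod.QoDReport`. The whole run is deterministic and keeps
every input row — cleaning only blanks values, never drops records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .ckd import CKDTable, VariableSpec, load_ckd, normalize_unit
from .convert import EMPTY_UNIT_POLICIES, standardize
from .fuzzy import DEFAULT_THRESHOLD, METHODS, match_unit
from .preprocess import (
    DEFAULT_MEANINGLESS_TOKENS,
    Missing,
    MissingReason,
    RAW_CSV_COLUMNS,
    RawRecord,
    clean_unit_token,
    coerce_numeric,
)
from .qod import QoDReport, stage_report
from .ranges import DEFAULT_MAX_ABS_EXPONENT, magnitude_correct

logger = logging.getLogger("ehrclean")

__all__ = [
    "RunConfig",
    "extract_records",
    "records_from_frame",
    "clean_variable",
    "run_pipeline",
    "CleanRecord",
]

#: Audit columns appended (per value column) to the cleaned output.
_VALUE_OUT_COLS = ("value_clean", "missing_reason", "exponent_applied")


@dataclass
class RunConfig:
    """Everything a cleaning run needs; the pipeline holds no other state."""

    ckd_path: str | Path | None = None
    input_path: str | Path | None = None
    output_path: str | Path | None = None
    report_path: str | Path | None = None
    variable_codes: list[str] = field(default_factory=list)
    value_columns: list[str] = field(default_factory=lambda: ["num1"])
    unit_column: str = "unit"
    code_column: str = "test_code"
    unit_match_threshold: float = DEFAULT_THRESHOLD
    empty_unit_policy: str = "assume_standard"
    max_abs_exponent: int = DEFAULT_MAX_ABS_EXPONENT
    meaningless_tokens: frozenset[str] = DEFAULT_MEANINGLESS_TOKENS
    similarity_method: str = "matching_blocks"

    def __post_init__(self) -> None:
        if not (0.0 < self.unit_match_threshold <= 1.0):
            raise ValueError("unit_match_threshold must be in (0, 1]")
        if self.empty_unit_policy not in EMPTY_UNIT_POLICIES:
            raise ValueError(f"unknown empty_unit_policy {self.empty_unit_policy!r}")
        if self.similarity_method not in METHODS:
            raise ValueError(f"unknown similarity_method {self.similarity_method!r}")
        if self.max_abs_exponent < 1:
            raise ValueError("max_abs_exponent must be >= 1")
        self.meaningless_tokens = frozenset(
            t.casefold() for t in self.meaningless_tokens
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON run config."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "meaningless_tokens" in raw:
            raw["meaningless_tokens"] = frozenset(raw["meaningless_tokens"])
        return cls(**raw)


@dataclass
class CleanRecord:
    """One record after full cleaning, with per-stage provenance."""

    record: RawRecord
    value: float | Missing
    unit: str
    source_unit: str | None
    unit_ratio: float | None
    exponent_applied: int
    value2: float | Missing | None = None
    exponent_applied2: int = 0


def extract_records(
    dataset: pd.DataFrame,
    variable_code: str,
    config: RunConfig | None = None,
) -> list[RawRecord]:
    """Rows whose test code equals ``variable_code``, in input order.

    An unknown code yields an empty list with a warning, not an error.
    """
    config = config or RunConfig()
    code_col = config.code_column
    if code_col not in dataset.columns:
        raise ValueError(f"input table has no {code_col!r} column")
    mask = dataset[code_col].astype(str).str.strip() == str(variable_code).strip()
    if not mask.any():
        logger.warning("no records found for variable code %r", variable_code)
    return records_from_frame(dataset.loc[mask], config)


def records_from_frame(frame: pd.DataFrame, config: RunConfig | None = None) -> list[RawRecord]:
    """Build :class:`RawRecord` objects from a Table-1-shaped frame."""
    config = config or RunConfig()

    def cell(row, col) -> str:
        v = row.get(col, "")
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return str(v)

    records = []
    for _, row in frame.iterrows():
        records.append(
            RawRecord(
                patient_id=cell(row, "patient_id"),
                gp_id=cell(row, "gp_id"),
                birth_year=cell(row, "birth_year"),
                sex=cell(row, "sex"),
                test_code=cell(row, config.code_column),
                date=cell(row, "date"),
                year=cell(row, "year"),
                test_name=cell(row, "test_name"),
                value_token=cell(row, config.value_columns[0]),
                value2_token=cell(row, config.value_columns[1])
                if len(config.value_columns) > 1
                else "",
                unit_token=cell(row, config.unit_column),
            )
        )
    return records


def _clean_one_column(
    tokens: Sequence[str],
    units_clean: Sequence[str],
    spec: VariableSpec,
    config: RunConfig,
):
    """Run one value column through parse → match → convert → range-clean.

    Returns per-record dicts plus the four stage snapshots for this column.
    """
    std = spec.standard_unit.casefold()
    candidates = spec.unit_labels  # standard unit first
    snap_original: list = []
    snap_pre: list = []
    snap_unit: list = []
    snap_final: list = []
    comparable_raw: list[bool] = []
    rows: list[dict] = []

    for token, unit in zip(tokens, units_clean):
        value = coerce_numeric(token, config.meaningless_tokens)
        # Raw snapshot: only originally-blank cells are missing; cells with
        # unusable content are present-but-unjudgeable.
        if isinstance(value, Missing):
            if value.reason is MissingReason.ORIGINALLY_MISSING:
                snap_original.append(value)
            else:
                snap_original.append(math.inf)  # content present, never normal
            comparable_raw.append(False)
        else:
            snap_original.append(value)
            unit_cf = normalize_unit(unit).casefold()
            comparable_raw.append(
                unit_cf == std
                or (unit_cf == "" and config.empty_unit_policy == "assume_standard")
            )
        snap_pre.append(value)

        if unit == "":
            match = None
        else:
            match = match_unit(
                unit,
                candidates,
                threshold=config.unit_match_threshold,
                method=config.similarity_method,
            )
        sv = standardize(value, match, spec, policy=config.empty_unit_policy)
        snap_unit.append(sv.value)

        cleaned = magnitude_correct(sv.value, spec, config.max_abs_exponent)
        snap_final.append(cleaned.value)

        rows.append(
            {
                "value_clean": cleaned.value,
                "missing_reason": (
                    cleaned.value.reason.value if isinstance(cleaned.value, Missing) else ""
                ),
                "exponent_applied": cleaned.exponent_applied,
                "range_class": cleaned.range_class,
                "matched_unit": sv.source_unit or "",
                "unit_ratio": match.ratio if match is not None else float("nan"),
                "unit_accepted": match.accepted if match is not None else None,
            }
        )

    snapshots = {
        "original": snap_original,
        "after_preprocessing": snap_pre,
        "after_unit_change": snap_unit,
        "after_all_steps": snap_final,
    }
    masks = {"original": comparable_raw, "after_preprocessing": comparable_raw}
    return rows, snapshots, masks


def clean_variable(
    records: Sequence[RawRecord],
    spec: VariableSpec,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, QoDReport]:
    """Clean all records of one variable; return audit table + QoD report.

    The output frame keeps every original column and appends, per value
    column, ``value_clean`` / ``missing_reason`` / ``exponent_applied``
    (prefixed for secondary columns), plus shared ``unit_clean``,
    ``matched_unit`` and ``unit_ratio`` audit columns. Row order and count
    are preserved.
    """
    config = config or RunConfig()
    n = len(records)
    units_clean = [
        clean_unit_token(r.unit_token, config.meaningless_tokens) for r in records
    ]

    col_tokens = {config.value_columns[0]: [r.value_token for r in records]}
    if len(config.value_columns) > 1:
        col_tokens[config.value_columns[1]] = [r.value2_token for r in records]

    all_snapshots = {s: [] for s in ("original", "after_preprocessing", "after_unit_change", "after_all_steps")}
    all_masks = {"original": [], "after_preprocessing": []}
    out = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "gp_id": [r.gp_id for r in records],
            "birth_year": [r.birth_year for r in records],
            "sex": [r.sex for r in records],
            config.code_column: [r.test_code for r in records],
            "date": [r.date for r in records],
            "year": [r.year for r in records],
            "test_name": [r.test_name for r in records],
        }
    )
    for i, col in enumerate(config.value_columns):
        rows, snapshots, masks = _clean_one_column(col_tokens[col], units_clean, spec, config)
        for s in all_snapshots:
            all_snapshots[s].extend(snapshots[s])
        for s in all_masks:
            all_masks[s].extend(masks[s])
        prefix = "" if i == 0 else f"{col}_"
        out[col] = col_tokens[col]
        out[f"{prefix}value_clean"] = [
            "" if isinstance(r["value_clean"], Missing) else repr(r["value_clean"])
            for r in rows
        ]
        out[f"{prefix}missing_reason"] = [r["missing_reason"] for r in rows]
        out[f"{prefix}exponent_applied"] = [r["exponent_applied"] for r in rows]
        if i == 0:
            out["unit"] = [r.unit_token for r in records]
            out["unit_clean"] = [spec.standard_unit] * n
            out["matched_unit"] = [r["matched_unit"] for r in rows]
            out["unit_ratio"] = [
                "" if math.isnan(r["unit_ratio"]) else f"{r['unit_ratio']:.6f}"
                for r in rows
            ]

    report = stage_report(all_snapshots, spec, comparable=all_masks)
    for stage in ("original", "after_preprocessing", "after_unit_change", "after_all_steps"):
        st = report[stage]
        logger.info(
            "variable=%s stage=%s n=%d missing=%d normal=%d plausible=%d",
            spec.variable_code, stage, st.n_total, st.n_missing, st.n_normal, st.n_plausible,
        )
    return out, report


def run_pipeline(config: RunConfig) -> dict[str, QoDReport]:
    """Run the full pipeline for every configured variable; write outputs.

    Variables are cleaned independently; a failure in one is logged and
    skipped so the rest still run. Returns the per-variable reports.
    """
    if config.ckd_path is None or config.input_path is None:
        raise ValueError("config must set ckd_path and input_path")
    ckd = load_ckd(config.ckd_path)
    dataset = pd.read_csv(config.input_path, dtype=str, keep_default_na=False)
    codes = config.variable_codes or [
        c for c in dataset[config.code_column].astype(str).str.strip().unique()
        if c in ckd.specs
    ]
    frames: list[pd.DataFrame] = []
    reports: dict[str, QoDReport] = {}
    for code in codes:
        try:
            spec = ckd.get(code)
            records = extract_records(dataset, code, config)
            cleaned, report = clean_variable(records, spec, config)
        except Exception:
            logger.exception("cleaning failed for variable %r; skipping", code)
            continue
        frames.append(cleaned)
        reports[code] = report
    if config.output_path is not None and frames:
        pd.concat(frames, ignore_index=True).to_csv(config.output_path, index=False)
    if config.report_path is not None and reports:
        from .qod import write_report_csv, write_report_json

        path = Path(config.report_path)
        if path.suffix.lower() == ".json":
            write_report_json(list(reports.values()), path)
        else:
            write_report_csv(list(reports.values()), path)
    return reports
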