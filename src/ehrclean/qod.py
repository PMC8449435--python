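"""Quality-of-data measures: completeness, correctness, plausibility.

Conventions (per the evaluation literature for EHR quality dimensions):

* completeness — the percentage of *missing* values (lower is better);
* correctness — the percentage of values inside the normal range, over all
  records, missing included (configurable to non-missing-only);
* plausibility — the percentage of *non-missing* values inside the extreme
  range; 100% by construction after full cleaning.

A :class:`QoDReport` collects these per pipeline stage (original, after
preprocessing, after unit change, after all steps) for one variable, the
shape in which cleaning studies tabulate before/after quality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ckd import VariableSpec
from .preprocess import Missing
from .ranges import classify_range, IMPLAUSIBLE, NORMAL

__all__ = [
    "STAGES",
    "StageStats",
    "QoDReport",
    "completeness",
    "correctness",
    "plausibility",
    "stage_report",
    "REPORT_CSV_COLUMNS",
]

STAGES = ("original", "after_preprocessing", "after_unit_change", "after_all_steps")

REPORT_CSV_COLUMNS = [
    "variable_code",
    "test_name",
    "n_obs",
    "miss_original_pct",
    "miss_preproc_pct",
    "miss_unit_pct",
    "miss_final_pct",
    "correct_original_pct",
    "correct_final_pct",
]


def _is_missing(v) -> bool:
    return isinstance(v, Missing) or v is None or (isinstance(v, float) and math.isnan(v))


def completeness(values: Sequence) -> float:
    """Percentage of missing values (the completeness measure; 0 is perfect)."""
    if len(values) == 0:
        raise ValueError("completeness undefined for an empty value list")
    return 100.0 * sum(_is_missing(v) for v in values) / len(values)


def correctness(
    values: Sequence,
    spec: VariableSpec,
    denominator: str = "all",
    comparable: Sequence[bool] | None = None,
) -> float:
    """Percentage of values within the normal range (inclusive bounds).

    ``values`` must already be in the standard unit. Missing values count in
    the denominator (``denominator="all"``, default) and never in the
    numerator; ``denominator="non_missing"`` restricts the base. At the raw
    stage, where some values sit in unconverted units, pass ``comparable``
    flags: a non-comparable value cannot be judged normal.
    """
    if len(values) == 0:
        raise ValueError("correctness undefined for an empty value list")
    if comparable is None:
        comparable = [True] * len(values)
    n_normal = sum(
        1
        for v, ok in zip(values, comparable)
        if ok and not _is_missing(v) and classify_range(float(v), spec) == NORMAL
    )
    if denominator == "all":
        base = len(values)
    elif denominator == "non_missing":
        base = sum(not _is_missing(v) for v in values)
        if base == 0:
            return float("nan")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * n_normal / base


def plausibility(
    values: Sequence,
    spec: VariableSpec,
    comparable: Sequence[bool] | None = None,
) -> float:
    """Percentage of non-missing values within the extreme range.

    Returns NaN (undefined) when every value is missing.
    """
    if len(values) == 0:
        raise ValueError("plausibility undefined for an empty value list")
    if comparable is None:
        comparable = [True] * len(values)
    present = [(v, ok) for v, ok in zip(values, comparable) if not _is_missing(v)]
    if not present:
        return float("nan")
    n_plaus = sum(
        1
        for v, ok in present
        if ok and classify_range(float(v), spec) != IMPLAUSIBLE
    )
    return 100.0 * n_plaus / len(present)


@dataclass(frozen=True)
class StageStats:
    """Counts for one pipeline stage of one variable."""

    stage: str
    n_total: int
    n_missing: int
    n_normal: int
    n_plausible: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("n_missing", "n_normal", "n_plausible"):
            v = getattr(self, name)
            if not (0 <= v <= self.n_total):
                raise ValueError(f"{name}={v} outside [0, n_total={self.n_total}]")
        if self.n_normal > self.n_plausible:
            raise ValueError("n_normal cannot exceed n_plausible (normal ⊆ extreme)")

    @property
    def missing_pct(self) -> float:
        return 100.0 * self.n_missing / self.n_total if self.n_total else 0.0

    @property
    def normal_pct(self) -> float:
        return 100.0 * self.n_normal / self.n_total if self.n_total else 0.0


@dataclass
class QoDReport:
    """Per-stage quality statistics for one variable.

    ``footnote`` records the policies that shape the numbers (raw-stage
    comparability rule, correctness denominator), since different studies
    compute these measures slightly differently.
    """

    variable_code: str
    test_name: str = ""
    stages: dict = field(default_factory=dict)
    footnote: str = (
        "Raw-stage correctness counts a value as normal only when its unit "
        "is already the standard unit; correctness denominator includes "
        "missing values."
    )

    def add(self, stats: StageStats) -> None:
        if self.stages:
            n0 = next(iter(self.stages.values())).n_total
            if stats.n_total != n0:
                raise ValueError(
                    f"inconsistent n_total across stages: {stats.n_total} != {n0}"
                )
        self.stages[stats.stage] = stats

    def __getitem__(self, stage: str) -> StageStats:
        return self.stages[stage]

    @property
    def n_obs(self) -> int:
        return next(iter(self.stages.values())).n_total if self.stages else 0

    def to_row(self) -> dict:
        """One CSV row mirroring the before/after quality table layout."""
        def pct(stage: str, attr: str) -> float:
            st = self.stages.get(stage)
            return round(getattr(st, attr), 2) if st is not None else float("nan")

        return {
            "variable_code": self.variable_code,
            "test_name": self.test_name,
            "n_obs": self.n_obs,
            "miss_original_pct": pct("original", "missing_pct"),
            "miss_preproc_pct": pct("after_preprocessing", "missing_pct"),
            "miss_unit_pct": pct("after_unit_change", "missing_pct"),
            "miss_final_pct": pct("after_all_steps", "missing_pct"),
            "correct_original_pct": pct("original", "normal_pct"),
            "correct_final_pct": pct("after_all_steps", "normal_pct"),
        }

    def to_dict(self) -> dict:
        return {
            "variable_code": self.variable_code,
            "test_name": self.test_name,
            "footnote": self.footnote,
            "stages": {
                s: {
                    "n_total": st.n_total,
                    "n_missing": st.n_missing,
                    "n_normal": st.n_normal,
                    "n_plausible": st.n_plausible,
                    "missing_pct": st.missing_pct,
                    "normal_pct": st.normal_pct,
                }
                for s, st in self.stages.items()
            },
        }


def stage_report(
    snapshots: Mapping[str, Sequence],
    spec: VariableSpec,
    comparable: Mapping[str, Sequence[bool]] | None = None,
    test_name: str = "",
) -> QoDReport:
    """Assemble a QoD report from per-stage value snapshots.

    ``snapshots`` maps stage name -> values (standard unit, except the
    pre-conversion stages, whose unconverted-unit values are masked via the
    optional per-stage ``comparable`` flags). All stages must hold the same
    record count.
    """
    report = QoDReport(variable_code=spec.variable_code, test_name=test_name or spec.variable_name)
    comparable = comparable or {}
    for stage in STAGES:
        if stage not in snapshots:
            continue
        values = snapshots[stage]
        mask = comparable.get(stage)
        mask = [True] * len(values) if mask is None else mask
        n_missing = sum(_is_missing(v) for v in values)
        n_normal = sum(
            1
            for v, ok in zip(values, mask)
            if ok and not _is_missing(v) and classify_range(float(v), spec) == NORMAL
        )
        n_plausible = sum(
            1
            for v, ok in zip(values, mask)
            if ok and not _is_missing(v) and classify_range(float(v), spec) != IMPLAUSIBLE
        )
        report.add(
            StageStats(
                stage=stage,
                n_total=len(values),
                n_missing=n_missing,
                n_normal=n_normal,
                n_plausible=n_plausible,
            )
        )
    return report


def write_report_csv(reports: Sequence[QoDReport], path: str | Path) -> None:
    """Write one row per variable in the before/after table layout."""
    rows = [r.to_row() for r in reports]
    pd.DataFrame(rows, columns=REPORT_CSV_COLUMNS).to_csv(path, index=False)


def write_report_json(reports: Sequence[QoDReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
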