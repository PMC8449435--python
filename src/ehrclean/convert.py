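"""Unit conversion: rescale every value into the variable's standard unit.

After fuzzy repair each record carries either a matched CKD unit, an empty
unit token, or a rejected match. Matched values are multiplied by the CKD
conversion rate; rejected units make the value missing; empty units follow
a policy switch — ``assume_standard`` (default) trusts that unit-less
entries were recorded in the standard unit, ``strict`` discards them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ckd import VariableSpec
from .fuzzy import MatchResult
from .preprocess import Missing, MissingReason

__all__ = ["StandardizedValue", "standardize", "EMPTY_UNIT_POLICIES"]

EMPTY_UNIT_POLICIES = ("assume_standard", "strict")


@dataclass(frozen=True)
class StandardizedValue:
    """A value in the standard unit (or missing), with its source unit."""

    value: float | Missing
    unit: str
    source_unit: str | None = None
    rate_applied: float = 1.0


def standardize(
    value: float | Missing,
    match: MatchResult | None,
    spec: VariableSpec,
    policy: str = "assume_standard",
) -> StandardizedValue:
    """Convert one (value, matched-unit) pair into the standard unit.

    ``match is None`` encodes an empty unit token. Missing values pass
    through with their original reason; a rejected match yields
    ``Missing(unmatched_unit)`` under either policy.
    """
    if policy not in EMPTY_UNIT_POLICIES:
        raise ValueError(f"unknown empty-unit policy {policy!r}")
    std = spec.standard_unit
    if isinstance(value, Missing):
        return StandardizedValue(value, std, None)
    if match is None:
        if policy == "assume_standard":
            return StandardizedValue(float(value), std, None, 1.0)
        return StandardizedValue(Missing(MissingReason.UNMATCHED_UNIT), std, None)
    if not match.accepted or match.best_candidate is None:
        return StandardizedValue(Missing(MissingReason.UNMATCHED_UNIT), std, None)
    rate = spec.rate_for(match.best_candidate)
    return StandardizedValue(float(value) * rate, std, match.best_candidate, rate)
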