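"""Range-based value cleaning: magnitude correction and outlier removal.

Order-of-magnitude entry errors (a blood pressure typed as 9 or 16000
instead of 90 or 160) are repaired by the power-of-ten shift that brings
the value closest to the normal range, provided the shifted value lands
inside the biologically plausible (extreme) range. Values no shift can
rescue are outliers and become missing. Values already inside the extreme
range are never touched: a genuinely sick patient's extreme-but-plausible
reading is data, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ckd import VariableSpec
from .preprocess import Missing, MissingReason

__all__ = [
    "RangeClass",
    "CleanedValue",
    "classify_range",
    "magnitude_correct",
    "shift_by_power_of_ten",
    "DEFAULT_MAX_ABS_EXPONENT",
]

#: Widest power-of-ten shift attempted; generous for keystroke errors while
#: refusing absurd rescues (a value off by 10^7 is not a typo'd zero).
DEFAULT_MAX_ABS_EXPONENT = 6

NORMAL = "normal"
EXTREME_BUT_PLAUSIBLE = "extreme_but_plausible"
IMPLAUSIBLE = "implausible"
RangeClass = str


def classify_range(value: float, spec: VariableSpec) -> RangeClass:
    """Place a standard-unit value w.r.t. the normal and extreme ranges.

    Both ranges are closed intervals: boundary values count as inside.
    """
    if spec.normal_range.contains(value):
        return NORMAL
    if spec.extreme_range.contains(value):
        return EXTREME_BUT_PLAUSIBLE
    return IMPLAUSIBLE


@dataclass(frozen=True)
class CleanedValue:
    """Result of magnitude correction for one value.

    ``exponent_applied`` is the k with output = input * 10**k (0 when the
    value was left untouched); any surviving value is guaranteed to lie in
    the extreme range.
    """

    value: float | Missing
    exponent_applied: int
    range_class: RangeClass


def shift_by_power_of_ten(value: float, k: int) -> float:
    """``value * 10**k``, dividing for negative k (90 / 100 is exactly 0.9,
    while 90 * 0.01 carries a one-ulp residue into the audit trail)."""
    return value * 10.0**k if k >= 0 else value / 10.0 ** (-k)


def _distance_to_normal(value: float, spec: VariableSpec) -> float:
    lo, hi = spec.normal_range.min, spec.normal_range.max
    if value < lo:
        return lo - value
    if value > hi:
        return value - hi
    return 0.0


def magnitude_correct(
    value: float | Missing,
    spec: VariableSpec,
    max_abs_exponent: int = DEFAULT_MAX_ABS_EXPONENT,
) -> CleanedValue:
    """Repair a power-of-ten entry error, or declare the value an outlier.

    Policy, in order:

    * missing input passes through unchanged;
    * values inside the extreme range (normal or extreme-but-plausible)
      are never shifted;
    * otherwise every k in {-K..K}\\{0} is tried; among shifts landing
      inside the extreme range the one closest to the normal range wins
      (ties: smaller ``|k|``, then negative k — trailing extra zeros being
      the archetypal entry error);
    * if no shift lands inside the extreme range the value becomes
      ``Missing(outlier)``.

    Sign errors are not magnitude errors: a non-positive value for a
    variable whose plausible range is positive is an outlier outright
    (no power of ten changes sign or rescues zero).
    """
    if isinstance(value, Missing):
        return CleanedValue(value, 0, IMPLAUSIBLE)
    value = float(value)
    cls = classify_range(value, spec)
    if cls != IMPLAUSIBLE:
        return CleanedValue(value, 0, cls)
    if value <= 0 and spec.extreme_range.min > 0:
        return CleanedValue(Missing(MissingReason.OUTLIER), 0, IMPLAUSIBLE)
    if value >= 0 and spec.extreme_range.max < 0:
        return CleanedValue(Missing(MissingReason.OUTLIER), 0, IMPLAUSIBLE)
    best: tuple[float, int, int] | None = None  # (dist, |k|, k-sign-order)
    best_k = 0
    best_value = None
    for k in range(-max_abs_exponent, max_abs_exponent + 1):
        if k == 0:
            continue
        shifted = shift_by_power_of_ten(value, k)
        if not spec.extreme_range.contains(shifted):
            continue
        key = (_distance_to_normal(shifted, spec), abs(k), 0 if k < 0 else 1)
        if best is None or key < best:
            best = key
            best_k = k
            best_value = shifted
    if best is None:
        return CleanedValue(Missing(MissingReason.OUTLIER), 0, IMPLAUSIBLE)
    return CleanedValue(best_value, best_k, classify_range(best_value, spec))
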