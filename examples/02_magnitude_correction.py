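"""Correct power-of-ten entry errors and remove implausible outliers.

A blood pressure recorded as 9 or 16000 is a keystroke error; shifting by
a power of ten brings it back toward the normal range (60-200 mmHg). A
value like 3000 has no shift that lands inside the biologically plausible
range (40-260 mmHg), so it becomes missing instead of being guessed at.
"""

from pathlib import Path

from ehrclean import load_ckd, magnitude_correct
from ehrclean.preprocess import Missing

ckd = load_ckd(Path(__file__).parent / "example_ckd.csv")
bp = ckd.get("BP")

print(f"blood pressure: normal {bp.normal_range.min:g}-{bp.normal_range.max:g}, "
      f"plausible {bp.extreme_range.min:g}-{bp.extreme_range.max:g} mmHg")
for raw in [9, 16000, 3000, 113, 250]:
    c = magnitude_correct(raw, bp)
    if isinstance(c.value, Missing):
        print(f"  {raw:>6} -> missing ({c.value.reason.value})")
    else:
        shift = f"x10^{c.exponent_applied}" if c.exponent_applied else "untouched"
        print(f"  {raw:>6} -> {c.value:g} ({shift}, {c.range_class})")

# 113 is already normal and 250 is extreme-but-plausible (a real patient
# can have it), so neither is altered; only implausible values are shifted
# or, failing that, removed.
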