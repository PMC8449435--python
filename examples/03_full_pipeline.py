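"""Run the whole cleaning pipeline on a synthetic dirty table.

Generates 1000 clean creatinine records, injects a labeled mix of the
error taxonomy (unit typos, meaningless units, alternate valid units,
power-of-ten shifts, implausible values, meaningless value tokens), cleans
them, and prints the per-stage quality report.
"""

from pathlib import Path

from ehrclean import (
    CorruptionConfig,
    clean_variable,
    corrupt_records,
    generate_clean_records,
    load_ckd,
)
from ehrclean.pipeline import records_from_frame

ckd = load_ckd(Path(__file__).parent / "example_ckd.csv")
spec = ckd.get("57139A.B")

clean = generate_clean_records(spec, 1000, seed=7)
dirty, truth = corrupt_records(
    clean,
    spec,
    CorruptionConfig(
        p_unit_typo=0.05, p_unit_meaningless=0.03, p_alternate_valid_unit=0.05,
        p_magnitude_error=0.05, p_implausible=0.03, p_meaningless_value=0.03,
        seed=8,
    ),
)
print("injected errors:")
print(truth["error_type"].replace("", "none").value_counts().to_string())

cleaned, report = clean_variable(records_from_frame(dirty), spec)

print(f"\nquality of {spec.variable_name} ({report.n_obs} records) per stage:")
print(f"{'stage':<22}{'missing %':>10}{'normal %':>10}{'plausible':>10}")
for stage, st in report.stages.items():
    plaus = st.n_plausible
    print(f"{stage:<22}{st.missing_pct:>10.2f}{st.normal_pct:>10.2f}{plaus:>10}")

final = report["after_all_steps"]
print(
    f"\nafter cleaning, all {final.n_total - final.n_missing} surviving values "
    "lie inside the biologically plausible range; missingness grew only by "
    "the values nothing could rescue (implausible outliers, meaningless "
    "tokens, unrecognizable units)."
)
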