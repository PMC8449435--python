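"""Repair misspelled unit strings against a variable's legitimate units.

Each raw unit token is scored against every unit the clinical knowledge
table allows for the variable; the best-scoring unit wins unless even it
falls below the 0.5 acceptance threshold, in which case the token is
declared unrecognizable and the value will later be dropped.
"""

from pathlib import Path

from ehrclean import load_ckd, match_unit, similarity_ratio

ckd = load_ckd(Path(__file__).parent / "example_ckd.csv")
creatinine = ckd.get("57139A.B")

print("similarity of two classic unit typos (default normalization):")
for raw, correct in [("106/L", "X10exp6/L"), ("mmol/LsOms", "mmol/L")]:
    print(f"  {raw!r:14} vs {correct!r:14} -> {similarity_ratio(raw, correct):.2f}")

print("\nmatching raw tokens against creatinine's units", creatinine.unit_labels)
for token in ["mmol/L", "mmol/LsOms", "mg/dl", "??", "zzz"]:
    m = match_unit(token, creatinine.unit_labels, threshold=0.5)
    verdict = f"-> {m.best_candidate!r}" if m.accepted else "-> rejected (unit unusable)"
    print(f"  {token!r:14} ratio={m.ratio:.2f} {verdict}")

# A ratio of 1.00 is an exact (case-insensitive) match; anything >= 0.5 is
# accepted as a repairable typo; below 0.5 the unit carries no information.
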