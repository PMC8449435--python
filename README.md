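# ehrclean

Automated, clinical-knowledge-driven cleaning of EHR measurement and
laboratory records.

Routinely collected primary-care data is full of entry errors that generic,
distribution-based cleaning tools handle badly: unit strings that are
misspelled (`mmol/LsOms`) or meaningless (`??`, `77`, `NULL`), the same
analyte reported in different units by different labs (creatinine in mg/dL,
mmol/L or mg/L), values typed with extra or missing zeros (a blood pressure
of `9` or `16,000`), and values that are simply impossible. Because healthy
and severely ill patients legitimately coexist in primary-care registries,
outlier detection based on the observed distribution flags real patients as
errors. `ehrclean` instead drives every decision from a curated **Clinical
Knowledge Database (CKD)** — a small table holding, per variable, the
legitimate units with their conversion rates, the standard unit, the normal
(reference) range and the extreme (biologically plausible) range. It is
aimed at clinical researchers and registry maintainers who need thousands of
variables cleaned reproducibly without per-variable manual work.

## Method

For each variable, records pass through four deterministic stages:

1. **Preprocessing** — value tokens are stripped of unexpected characters
   and coerced to numbers (` 1 650 ` → 1650, `12,5` → 12.5, `16,000` →
   16000); meaningless tokens (`NULL`, `na`, `,`, …) become missing.
2. **Fuzzy unit repair** — each unit token is compared with every
   legitimate unit *u* of the variable using a length-normalized
   Levenshtein similarity. Two normalizations are available: the default

   `ratio(V, W) = (|V| + |W| − Lev₂(V, W)) / (|V| + |W|)`,

   where `Lev₂` is the edit distance with substitution cost 2 (the
   normalization used by the classic fuzzy-matching libraries), and the
   textbook form `1 − Lev(V, W) / max(|V|, |W|)`. The best-scoring unit
   replaces the token if its ratio reaches the threshold (default 0.5);
   otherwise the unit is unusable and the value becomes missing.
3. **Unit conversion** — the value is multiplied by the CKD rate of its
   (repaired) unit into the standard unit, e.g. ×18 for glucose mmol/L →
   mg/dL but ×11.312 for creatinine.
4. **Range cleaning** — values inside the extreme range are left alone
   (an extreme-but-plausible reading is a sick patient, not an error);
   implausible values are shifted by the power of ten 10ᵏ (|k| ≤ 6) that
   brings them closest to the normal range, and kept only if the shifted
   value is plausible; everything else becomes missing as an outlier.

Per-stage snapshots yield a quality report with the three measures:
**completeness** (percentage of missing values), **correctness**
(percentage inside the normal range) and **plausibility** (percentage of
non-missing values inside the extreme range — 100% by construction after
cleaning). Nothing is ever imputed; cleaning only repairs or blanks values,
and never drops a row.

A synthetic-data module generates registry-shaped tables with a labeled,
controllable mix of exactly these error types, so the whole pipeline is
testable without access to restricted patient data.

## Worked example

```bash
python examples/02_magnitude_correction.py
```

```
blood pressure: normal 60-200, plausible 40-260 mmHg
       9 -> 90 (x10^1, normal)
   16000 -> 160 (x10^-2, normal)
    3000 -> missing (outlier)
     113 -> 113 (untouched, normal)
     250 -> 250 (untouched, extreme_but_plausible)
```

The entry errors 9 and 16000 are restored to 90 and 160 mmHg by a single
power-of-ten shift; 3000 stays implausible under every shift (30 and 300
are both outside 40–260) and is removed; plausible values — including the
extreme-but-real 250 — are never touched.

`examples/03_full_pipeline.py` runs the full pipeline on 1000 synthetic
creatinine records with ~23% injected errors and prints the stage report:

```
stage                  missing %  normal % plausible
original                    0.00     81.40       821
after_preprocessing         2.80     81.40       821
after_unit_change           2.80     89.00       897
after_all_steps             5.40     93.90       946
```

Missingness grows only by what nothing could rescue (meaningless tokens,
implausible outliers), while correctness rises as units are harmonized and
magnitude errors repaired; every surviving value is plausible.

The same pipeline is available from the shell:

```bash
ehrclean clean --ckd examples/example_ckd.csv --input raw.csv \
    --variable 57139A.B --out cleaned.csv --report report.csv
ehrclean synth --ckd examples/example_ckd.csv --variable 57139A.B \
    --n 1000 --seed 7 --out dirty.csv --truth-out truth.csv
```

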