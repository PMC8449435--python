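# Methods

This note documents the model behind `ehrclean`, the parameters that
matter, the numerical and policy choices made where the procedure was
genuinely open, and what the synthetic-data tests do and do not establish
about real registry data.

## The cleaning model

The pipeline assumes that errors in measurement/laboratory exports fall
into a small taxonomy, each with a knowledge-driven repair:

| error | example | repair |
|---|---|---|
| meaningless value token | `NULL`, `,`, `n` | missing (`meaningless_token`) |
| ambiguous numeric token | `1.2.3` | missing (`unparseable_number`) |
| misspelled unit | `mmol/LsOms` | fuzzy match to a legitimate unit |
| meaningless unit | `??`, `77` | blank; empty-unit policy applies |
| alternate legitimate unit | creatinine in mmol/L | multiply by CKD rate |
| magnitude (power-of-ten) error | BP of 9 or 16000 | shift by 10ᵏ toward normal |
| implausible value | BP of 3000 | missing (`outlier`) |

All knowledge lives in the CKD table (units, rates, standard unit, normal
and extreme ranges, both ranges expressed in the standard unit). The
pipeline itself is variable-agnostic and fully deterministic: no
distributional estimates, no imputation, no randomness.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `unit_match_threshold` | 0.5 | minimum similarity ratio to accept a unit repair; below it the unit is treated as carrying no information |
| `similarity_method` | `matching_blocks` | substitution-cost-2 normalization `(|V|+|W|−Lev₂)/(|V|+|W|)`; the textbook `1 − Lev/max(|V|,|W|)` (`printed_formula`) is selectable. The default reproduces the worked unit-check scores (0.71, 0.75) that this pipeline is calibrated against; the textbook form yields 0.56/0.60 on the same pairs |
| `empty_unit_policy` | `assume_standard` | blank units are common in exports and overwhelmingly mean "recorded in the default unit"; `strict` discards such values instead |
| `max_abs_exponent` | 6 | widest power-of-ten shift attempted; generous for keystroke errors while refusing absurd rescues |
| `meaningless_tokens` | `"", ",", ".", "n", "null", "na", "nan", "?", "??", "-"` | casefolded; seeded from tokens observed in practice, extensible per run |

## Numerical and policy choices

* **Decimal/grouping separators.** Belgian exports mix comma decimals with
  dotted decimals. When both `.` and `,` occur, the rightmost is the
  decimal mark. A lone comma is a decimal mark *unless* followed by exactly
  three digits at the end of the token (`16,000` → 16000, `12,5` → 12.5).
  Multiple dots, or digits with embedded signs, have no unambiguous reading
  and become missing rather than guessed.
* **Magnitude-correction objective.** Among candidate exponents whose
  shifted value lands inside the extreme range, the one minimizing the
  Euclidean distance to the normal interval wins (0 if inside). Ties break
  to smaller |k|, then to negative k, since extra trailing zeros are the
  archetypal keystroke error. Negative k is applied as division so the
  audit value carries no spurious ulp residue (90/100 = 0.9 exactly).
* **Plausible values are never shifted.** A value inside the extreme range
  is left untouched even when outside the normal range: registries contain
  genuinely sick patients, and "correcting" their extremes would corrupt
  data. The acceptance test for a shift is landing inside the *extreme*
  range (plausibility), not the normal range.
* **Sign errors are not magnitude errors.** A non-positive value for a
  variable with a positive plausible range becomes missing without any
  shift attempt; no power of ten changes sign or rescues zero.
* **Unit-label comparison** is case-insensitive on trimmed,
  whitespace-collapsed tokens (sources print `Mg/dL` and `mg/dL`
  interchangeably); original casing is preserved for display. Fuzzy-match
  ties at equal ratio break to smaller plain Levenshtein distance, then to
  CKD order with the standard unit first.
* **Quality-measure denominators.** Correctness uses all records (missing
  included) so completeness and correctness share a base; a
  `non_missing` denominator is available. At the pre-conversion stages a
  value can only count as normal when its raw unit already is the standard
  unit (or is blank under `assume_standard`); values in other units are not
  comparable to the ranges and count as not-normal. Plausibility uses
  non-missing values only and is undefined (NaN) when everything is
  missing. Range membership is inclusive at both boundaries.
* **CKD validation is strict.** Exactly one unit per variable may carry
  rate 1 (the standard unit, tolerance 1e-12); the normal range must nest
  inside the extreme range; duplicate variable codes in non-contiguous CSV
  groups are a hard error, since the CKD is curated knowledge and ambiguity
  there is a curation bug. Ranges are per-variable, not per-unit, and are
  stored in the standard unit because range checks run after conversion.
* **Two value columns.** Exports carry two numeric fields per row; by
  default only the first is cleaned, and when the second is configured it
  is cleaned independently against the same spec (their joint semantics,
  e.g. systolic/diastolic pairs, are out of scope).

## The synthetic-data generator

`generate_clean_records` samples values uniformly inside the normal range —
range membership is the only property the pipeline inspects, and uniform
sampling maximizes boundary coverage — with the standard unit on every row.
`corrupt_records` then gives each selected row exactly one labeled error:
unit typos are built from the same edit operations the matcher scores
(rerolled if they happen to spell a *different* legitimate unit, which
would be a relabeling, not a typo); alternate-unit corruption re-expresses
the value losslessly in a non-standard CKD unit; implausible values are
placed beyond the reach of every |k| ≤ 6 shift; magnitude errors use
k ∈ {±1, ±2} by default.

What passing these tests shows: the pipeline inverts every recoverable
corruption exactly (to 1e-9 relative) when the repair is unambiguous —
unit typos above the threshold on single-unit specs, alternate-unit
re-expressions, and magnitude errors on specs whose extreme span is below
a factor of 10 (which makes the valid exponent unique). What it does not
show: behavior on real free-text idiosyncrasies outside the modeled
taxonomy (composite units, comments in value cells, longitudinal
inconsistencies within a patient), realistic value distributions, or unit
typos that are genuinely ambiguous between two legitimate units of one
variable — there the matcher picks the closer unit, which can be wrong.

## Problem sizes

The test suite exercises the edit-distance implementation exhaustively
against a brute-force transcription of the recursive definition for all
string pairs up to length 6 over a 3-letter alphabet (~600k unordered
pairs), and end-to-end properties (determinism, idempotence, 100%
post-clean plausibility, monotone missingness, exact magnitude recovery)
on synthetic tables of 150–1000 records per scenario with fixed seeds.

## Known limitations

* Conversions are purely multiplicative; affine transforms (temperature
  scales) do not fit the single-rate CKD schema and are rejected territory.
* No longitudinal or cross-variable consistency rules (e.g. IF–THEN checks
  between related analytes); no deduplication; no date validation.
* Fuzzy repair considers only character edits — no phonetic or semantic
  similarity — and the 0.5 threshold is a pragmatic operating point, not an
  optimum derived from labeled data.
* Raw-stage correctness for values in non-standard units is a reporting
  policy (counted not-normal), since pre-conversion comparability is
  undefined; the report footnote records this.
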