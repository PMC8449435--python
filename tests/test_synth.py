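"""Synthetic dirty-record generation and pipeline round trips."""

import numpy as np
import pandas as pd
import pytest

from ehrclean.pipeline import clean_variable, records_from_frame
from ehrclean.ranges import classify_range, NORMAL
from ehrclean.synth import (
    CorruptionConfig,
    corrupt_records,
    generate_clean_records,
)


class TestGenerateCleanRecords:
    def test_reproducible_given_seed(self, creatinine_spec):
        a = generate_clean_records(creatinine_spec, 100, seed=7)
        b = generate_clean_records(creatinine_spec, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, creatinine_spec):
        a = generate_clean_records(creatinine_spec, 100, seed=7)
        b = generate_clean_records(creatinine_spec, 100, seed=8)
        assert not a["num1"].equals(b["num1"])

    def test_all_values_classify_normal(self, creatinine_spec):
        frame = generate_clean_records(creatinine_spec, 200, seed=1)
        for token in frame["num1"]:
            assert classify_range(float(token), creatinine_spec) == NORMAL
        assert (frame["unit"] == creatinine_spec.standard_unit).all()

    def test_zero_records_rejected(self, creatinine_spec):
        with pytest.raises(ValueError, match="positive"):
            generate_clean_records(creatinine_spec, 0, seed=1)


class TestCorruptRecords:
    def test_zero_probabilities_is_identity(self, creatinine_spec):
        clean = generate_clean_records(creatinine_spec, 50, seed=3)
        dirty, truth = corrupt_records(clean, creatinine_spec, CorruptionConfig(seed=3))
        pd.testing.assert_frame_equal(dirty, clean)
        assert (truth["error_type"] == "").all()

    def test_reproducible_given_seed(self, creatinine_spec):
        clean = generate_clean_records(creatinine_spec, 100, seed=5)
        cfg = CorruptionConfig(p_unit_typo=0.2, p_magnitude_error=0.2, seed=11)
        d1, t1 = corrupt_records(clean, creatinine_spec, cfg)
        d2, t2 = corrupt_records(clean, creatinine_spec, cfg)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_each_corrupted_record_has_one_label(self, creatinine_spec):
        clean = generate_clean_records(creatinine_spec, 300, seed=9)
        cfg = CorruptionConfig(
            p_unit_typo=0.1, p_unit_meaningless=0.1, p_alternate_valid_unit=0.1,
            p_magnitude_error=0.1, p_implausible=0.1, p_meaningless_value=0.1,
            seed=9,
        )
        dirty, truth = corrupt_records(clean, creatinine_spec, cfg)
        assert len(truth) == len(clean)
        changed = (dirty["num1"] != clean["num1"]) | (dirty["unit"] != clean["unit"])
        labeled = truth["error_type"] != ""
        # a changed row always carries a label; a labeled unit typo may by
        # chance reconstruct a valid casing, so allow label-without-change
        assert set(truth.loc[np.flatnonzero(changed), "error_type"]) <= set(
            truth.loc[labeled, "error_type"]
        )
        assert (truth.loc[~labeled, "exponent"] == 0).all()

    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="sum"):
            CorruptionConfig(p_unit_typo=0.7, p_magnitude_error=0.6)
        with pytest.raises(ValueError, match="exclude 0"):
            CorruptionConfig(exponent_choices=(0, 1))


class TestPipelineRoundTrip:
    def _clean(self, frame, spec):
        cleaned, report = clean_variable(records_from_frame(frame), spec)
        values = [
            float(v) if v != "" else None for v in cleaned["value_clean"]
        ]
        return cleaned, report, values

    def test_recoverable_corruptions_are_inverted_exactly(self, bp_spec, creatinine_spec):
        """Unit typos, alternate valid units and unique-exponent magnitude
        errors are all undone to the true standard-unit value (1e-9 rel)."""
        # typos + magnitude errors: single-unit spec with extreme span < 10,
        # so neither the fuzzy match nor the exponent is ever ambiguous
        clean = generate_clean_records(bp_spec, 400, seed=21)
        cfg = CorruptionConfig(
            p_unit_typo=0.2, p_magnitude_error=0.2,
            exponent_choices=(-2, -1, 1, 2), typo_edits=(1,), seed=22,
        )
        dirty, truth = corrupt_records(clean, bp_spec, cfg)
        _, _, values = self._clean(dirty, bp_spec)
        n_checked = 0
        for i, row in truth.iterrows():
            if row["error_type"] in ("unit_typo", "magnitude_error"):
                assert values[i] == pytest.approx(row["true_value"], rel=1e-9)
                n_checked += 1
        assert n_checked > 50

        # values re-expressed in an alternate legitimate unit convert back
        clean = generate_clean_records(creatinine_spec, 200, seed=23)
        cfg = CorruptionConfig(p_alternate_valid_unit=0.5, seed=24)
        dirty, truth = corrupt_records(clean, creatinine_spec, cfg)
        _, _, values = self._clean(dirty, creatinine_spec)
        alt = truth["error_type"] == "alternate_valid_unit"
        assert alt.sum() > 30
        for i in truth.index[alt]:
            assert values[i] == pytest.approx(truth.loc[i, "true_value"], rel=1e-9)

    def test_magnitude_recovery_is_exact_for_narrow_span_spec(self, bp_spec):
        """Extreme span 6.5 < 10: every injected x10^k (k in +-1, +-2) is
        recovered exactly, for all 500 corrupted records."""
        clean = generate_clean_records(bp_spec, 500, seed=33)
        cfg = CorruptionConfig(
            p_magnitude_error=1.0, exponent_choices=(-2, -1, 1, 2), seed=34
        )
        dirty, truth = corrupt_records(clean, bp_spec, cfg)
        assert (truth["error_type"] == "magnitude_error").all()
        cleaned, _, values = self._clean(dirty, bp_spec)
        for i, row in truth.iterrows():
            assert values[i] == pytest.approx(row["true_value"], rel=1e-9)
            assert cleaned.loc[i, "exponent_applied"] == -row["exponent"]

    def test_implausible_and_meaningless_end_missing(self, creatinine_spec):
        clean = generate_clean_records(creatinine_spec, 300, seed=41)
        cfg = CorruptionConfig(p_implausible=0.3, p_meaningless_value=0.3, seed=42)
        dirty, truth = corrupt_records(clean, creatinine_spec, cfg)
        cleaned, _, _ = self._clean(dirty, creatinine_spec)
        for i, row in truth.iterrows():
            if row["error_type"] == "implausible":
                assert cleaned.loc[i, "missing_reason"] == "outlier"
            elif row["error_type"] == "meaningless_value":
                assert cleaned.loc[i, "missing_reason"] == "meaningless_token"

    def test_post_clean_plausibility_always_100(self, ckd_table):
        """Whatever is thrown at the pipeline, surviving values lie in the
        extreme range."""
        for spec in ckd_table:
            clean = generate_clean_records(spec, 200, seed=51)
            cfg = CorruptionConfig(
                p_unit_typo=0.1, p_unit_meaningless=0.1, p_alternate_valid_unit=0.1,
                p_magnitude_error=0.2, p_implausible=0.15, p_meaningless_value=0.1,
                seed=52,
            )
            dirty, _ = corrupt_records(clean, spec, cfg)
            _, report, values = self._clean(dirty, spec)
            for v in values:
                if v is not None:
                    assert spec.extreme_range.contains(v)
            final = report["after_all_steps"]
            assert final.n_plausible == final.n_total - final.n_missing

    def test_completeness_non_decreasing_across_stages(self, creatinine_spec):
        clean = generate_clean_records(creatinine_spec, 300, seed=61)
        cfg = CorruptionConfig(
            p_unit_meaningless=0.1, p_implausible=0.1, p_meaningless_value=0.1,
            seed=62,
        )
        dirty, _ = corrupt_records(clean, creatinine_spec, cfg)
        _, report, _ = self._clean(dirty, creatinine_spec)
        pcts = [report[s].missing_pct for s in
                ("original", "after_preprocessing", "after_unit_change", "after_all_steps")]
        assert pcts == sorted(pcts)
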