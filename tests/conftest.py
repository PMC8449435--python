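"""Shared fixtures: small CKD specs and a raw-export-shaped table."""

from __future__ import annotations

import pandas as pd
import pytest

from ehrclean.ckd import CKDTable, UnitEntry, ValueRange, VariableSpec


@pytest.fixture
def creatinine_spec() -> VariableSpec:
    """Serum creatinine: standard mg/dL, normal 0.6-1.3, plausible 0.1-5."""
    return VariableSpec(
        variable_code="57139A.B",
        variable_name="Creatinine",
        standard_unit="Mg/dL",
        units=(
            UnitEntry("Mg/dL", 1.0),
            UnitEntry("Mmol/L", 11.312),
            UnitEntry("Mg/L", 0.1),
        ),
        normal_range=ValueRange(0.6, 1.3),
        extreme_range=ValueRange(0.1, 5.0),
    )


@pytest.fixture
def glucose_spec() -> VariableSpec:
    """Glucose: mmol/L converts to mg/dL with rate 18."""
    return VariableSpec(
        variable_code="GLUC",
        variable_name="Glucose",
        standard_unit="mg/dL",
        units=(UnitEntry("mg/dL", 1.0), UnitEntry("mmol/L", 18.0)),
        normal_range=ValueRange(70.0, 100.0),
        extreme_range=ValueRange(10.0, 1000.0),
    )


@pytest.fixture
def bp_spec() -> VariableSpec:
    """Blood-pressure-like variable: normal 60-200, plausible 40-260 mmHg."""
    return VariableSpec(
        variable_code="BP",
        variable_name="Blood pressure",
        standard_unit="mmHg",
        units=(UnitEntry("mmHg", 1.0),),
        normal_range=ValueRange(60.0, 200.0),
        extreme_range=ValueRange(40.0, 260.0),
    )


@pytest.fixture
def ckd_table(creatinine_spec, glucose_spec, bp_spec) -> CKDTable:
    return CKDTable(
        specs={
            s.variable_code: s for s in (creatinine_spec, glucose_spec, bp_spec)
        }
    )


@pytest.fixture
def creatinine_csv(tmp_path):
    """Grouped-row CKD CSV for creatinine (blank range cells after row 1)."""
    path = tmp_path / "ckd.csv"
    path.write_text(
        "variable_code,variable_name,unit_label,rate_to_standard,standard_unit,"
        "normal_min,normal_max,extreme_min,extreme_max\n"
        "57139A.B,Creatinine,Mg/dL,1,Mg/dL,0.6,1.3,0.1,5\n"
        "57139A.B,,Mmol/L,11.312,,,,,\n"
        "57139A.B,,Mg/L,0.1,,,,,\n"
    )
    return path


@pytest.fixture
def raw_table() -> pd.DataFrame:
    """A raw measurement table shaped like a registry export."""
    rows = [
        # patient, gp, birth, sex, code, date, year, name, num1, num2, unit
        ("27898", "GP_981", "1957", "F", "S000000057", "09/08/2014", "2014", "", "1650", "", "cm"),
        ("27898", "GP_981", "1957", "F", "S000000058", "09/08/2014", "2014", "", "56.50", "", "kg"),
        ("27898", "GP_981", "1957", "F", "S000000057", "29/09/1995", "1995", "Height", "1630", "", "S002"),
        ("42716", "GP_981", "1963", "M", "S000000069", "18/11/2013", "2013", "", "113", "088", "mmHg"),
        ("61905", "GP_984", "1964", "F", "S000000069", "16/08/1993", "1993", "Blood pressure", "9050", "", "mmHg"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "gp_id", "birth_year", "sex", "test_code", "date",
            "year", "test_name", "num1", "num2", "unit",
        ],
    )
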