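"""Record validation, derived measures, duplicate resolution, filters, CSV I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infantfm.cohort import (
    CohortTable,
    SchemaError,
    ValidationError,
    compute_bmi,
    exclude_low_fm,
    load_cohort,
    resolve_duplicate,
    write_cohort,
)
from infantfm.synthetic import GeneratorSpec, generate_cohort

from conftest import make_record


class TestComputeBmi:
    @pytest.mark.parametrize(
        "weight,length,expected",
        [
            (4.0, 50.0, 16.0),
            (7.29, 65.02, 7.29 / 0.6502**2),
            (2.90, 47.24, 2.90 / 0.4724**2),
        ],
    )
    def test_values(self, weight, length, expected):
        assert compute_bmi(weight, length) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("weight,length", [(0, 50), (-1, 50), (4, 0), (4, -2)])
    def test_nonpositive_rejected(self, weight, length):
        with pytest.raises(ValidationError):
            compute_bmi(weight, length)

    @given(
        w=st.floats(0.5, 15), l=st.floats(30, 90), k=st.floats(0.1, 10)
    )
    @settings(derandomize=True, max_examples=50)
    def test_linear_in_weight(self, w, l, k):
        assert compute_bmi(k * w, l) == pytest.approx(k * compute_bmi(w, l), rel=1e-12)


class TestResolveDuplicate:
    def test_mean_of_two_within_tolerance(self):
        assert resolve_duplicate(6.0, 6.4, kind="skinfold").resolved == pytest.approx(6.2)

    def test_skinfold_gap_over_2mm_requires_third(self):
        with pytest.raises(ValidationError, match="third"):
            resolve_duplicate(6.0, 9.0, kind="skinfold")

    def test_third_reading_joins_the_mean(self):
        out = resolve_duplicate(6.0, 9.0, third=6.5, kind="skinfold")
        assert out.resolved == pytest.approx((6.0 + 9.0 + 6.5) / 3)

    def test_median_rule(self):
        out = resolve_duplicate(6.0, 9.0, third=6.5, kind="skinfold", rule="median")
        assert out.resolved == pytest.approx(6.5)

    def test_non_skinfold_never_needs_third(self):
        assert resolve_duplicate(30.0, 35.0, kind="other").resolved == pytest.approx(32.5)


class TestRecordInvariants:
    def test_preterm_rejected(self):
        with pytest.raises(ValidationError, match="gestational"):
            make_record(gestational_age_birth=35.0)

    def test_nonpositive_length_names_field(self):
        with pytest.raises(ValidationError, match="length"):
            make_record(length=0.0)

    def test_fm_exceeding_weight_rejected(self):
        with pytest.raises(ValidationError, match="fm_kg"):
            make_record(fm_kg=7.0, weight=5.0)

    def test_bmi_identity(self):
        rec = make_record(weight=7.29, length=65.02)
        assert rec.bmi == pytest.approx(7.29 / 0.6502**2, abs=1e-9)

    def test_fm_pct_derivation(self):
        rec = make_record(weight=5.0, fm_kg=0.25)
        assert rec.fm_pct == pytest.approx(5.0)

    def test_sex_encoding(self):
        assert make_record(sex="female").value_of("sex") == 0.0
        assert make_record(sex="male").value_of("sex") == 1.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CohortTable("3M", [make_record("x"), make_record("x")])

    def test_visit_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="visit"):
            CohortTable("6M", [make_record(visit="3M")])


class TestExcludeLowFm:
    def test_strict_boundary(self):
        below = make_record("lo", weight=5.0, fm_kg=0.245)  # 4.9%
        at = make_record("at", weight=5.0, fm_kg=0.250)  # exactly 5.0%
        cohort = CohortTable("3M", [below, at])
        kept, removed = exclude_low_fm(cohort)
        assert removed == 1
        assert [r.infant_id for r in kept] == ["at"]

    def test_empty_cohort(self):
        kept, removed = exclude_low_fm(CohortTable("3M", []))
        assert len(kept) == 0 and removed == 0

    def test_idempotent(self):
        cohort = generate_cohort(GeneratorSpec("1M", n=80, seed=5, low_fm_fraction=0.1))
        once, n1 = exclude_low_fm(cohort)
        twice, n2 = exclude_low_fm(once)
        assert n1 > 0 and n2 == 0
        assert [r.infant_id for r in twice] == [r.infant_id for r in once]

    def test_missing_fm_raises(self):
        rec = make_record(fm_kg=None)
        with pytest.raises(ValidationError, match="fm_kg"):
            exclude_low_fm(CohortTable("3M", [rec]))


class TestCsvIO:
    def test_round_trip_exact(self, tmp_path):
        cohort = generate_cohort(GeneratorSpec("6M", n=40, seed=8))
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = load_cohort(path, "6M")
        assert len(back) == len(cohort)
        for a, b in zip(cohort, back):
            for name in (
                "infant_id", "visit", "sex", "gestational_age_birth", "age_days",
                "weight", "length", "head_circ", "muac", "waist_circ",
                "thigh_circ", "calf_circ", "biceps_sf", "triceps_sf",
                "subscapular_sf", "waist_sf", "thigh_sf", "calf_sf", "fm_kg",
            ):
                assert getattr(a, name) == getattr(b, name), name

    def test_single_row_bmi_derived(self, tmp_path):
        cohort = CohortTable("6M", [make_record(visit="6M", weight=7.29, length=65.02)])
        path = tmp_path / "one.csv"
        write_cohort(cohort, path)
        back = load_cohort(path, "6M")
        assert back[0].bmi == pytest.approx(7.29 / 0.6502**2)

    def test_header_only(self, tmp_path):
        from infantfm.cohort import CSV_COLUMNS

        path = tmp_path / "empty.csv"
        path.write_text(",".join(CSV_COLUMNS) + "\n")
        assert len(load_cohort(path, "3M")) == 0

    def test_missing_column_named(self, tmp_path):
        from infantfm.cohort import CSV_COLUMNS

        cols = [c for c in CSV_COLUMNS if c != "length_cm"]
        path = tmp_path / "bad.csv"
        path.write_text(",".join(cols) + "\n")
        with pytest.raises(SchemaError, match="length_cm"):
            load_cohort(path, "3M")

    def test_bad_cell_names_row_and_field(self, tmp_path):
        cohort = CohortTable("3M", [make_record()])
        path = tmp_path / "cells.csv"
        write_cohort(cohort, path)
        text = path.read_text().replace("39.28", "not-a-number")
        path.write_text(text)
        with pytest.raises(ValidationError, match="waist_cm"):
            load_cohort(path, "3M")

    def test_zero_length_row_rejected(self, tmp_path):
        cohort = CohortTable("3M", [make_record()])
        path = tmp_path / "zlen.csv"
        write_cohort(cohort, path)
        path.write_text(path.read_text().replace("59.17", "0"))
        with pytest.raises(ValidationError, match="length"):
            load_cohort(path, "3M")

    def test_stated_bmi_ignored(self, tmp_path, caplog):
        import logging

        cohort = CohortTable("3M", [make_record()])
        path = tmp_path / "bmi.csv"
        write_cohort(cohort, path)
        lines = path.read_text().splitlines()
        lines[0] += ",bmi"
        lines[1] += ",99.9"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level(logging.WARNING):
            back = load_cohort(path, "3M")
        assert back[0].bmi < 20
        assert any("bmi" in m for m in caplog.messages)
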