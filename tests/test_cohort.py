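"""Cohort ingestion, validation, eligibility filtering and eye selection."""

import numpy as np
import pandas as pd
import pytest

from rocglm.cohort import (
    Cohort,
    CohortValidationError,
    ExclusionCriteria,
    SchemaError,
    apply_exclusions,
    cohort_from_frame,
    covariate_frame,
    read_cohort,
    select_one_eye_per_subject,
    write_cohort,
)

from conftest import make_eye_rows


class TestReadCohort:
    def test_toy_csv_round_trip(self, toy_csv):
        cohort = read_cohort(toy_csv)
        assert len(cohort) == 3
        rec = next(iter(cohort))
        assert rec.group == "glaucoma"
        assert rec.axial_length == pytest.approx(24.5)

    def test_schema_maps_foreign_column_names(self, tmp_path, toy_frame):
        renamed = toy_frame.rename(columns={"vfi": "VFI_percent"})
        path = tmp_path / "renamed.csv"
        renamed.to_csv(path, index=False)
        cohort = read_cohort(path, schema={"vfi": "VFI_percent"})
        assert cohort.frame["vfi"].tolist() == [90.0] * 3

    def test_missing_group_column_is_schema_error(self, tmp_path, toy_frame):
        path = tmp_path / "nogroup.csv"
        toy_frame.drop(columns=["group"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="group"):
            read_cohort(path)

    def test_out_of_range_vfi_names_row_and_field(self, tmp_path, toy_frame):
        toy_frame.loc[1, "vfi"] = 105.0
        path = tmp_path / "bad.csv"
        toy_frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=r"row 1: vfi"):
            read_cohort(path)

    def test_non_numeric_cell_reported_not_dropped(self, tmp_path, toy_frame):
        toy_frame["iop"] = toy_frame["iop"].astype(object)
        toy_frame.loc[2, "iop"] = "high"
        path = tmp_path / "nan.csv"
        toy_frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="iop"):
            read_cohort(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("subject_id,eye,group\n")
        with pytest.raises(ValueError, match="empty"):
            read_cohort(path)

    def test_duplicate_subject_eye_rejected(self, toy_frame):
        toy_frame.loc[1, "subject_id"] = "S0"
        with pytest.raises(CohortValidationError, match="duplicate"):
            cohort_from_frame(toy_frame)

    def test_write_read_round_trip(self, tmp_path, toy_frame):
        cohort = cohort_from_frame(toy_frame)
        path = tmp_path / "out.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back.frame, cohort.frame)


class TestExclusions:
    def test_low_signal_strength_excluded_with_named_rule(self):
        frame = make_eye_rows(2)
        frame.loc[0, "signal_strength_disc"] = 5.0
        retained, report = apply_exclusions(cohort_from_frame(frame))
        assert len(retained) == 1
        assert report.n_excluded == 1
        (entry,) = report.entries
        assert entry[0] == "S0"
        assert "signal strength < 6" in entry[2]

    def test_iop_exactly_21_retained(self):
        frame = make_eye_rows(1, iop=[21.0])
        retained, report = apply_exclusions(cohort_from_frame(frame))
        assert len(retained) == 1 and not report.entries

    @pytest.mark.parametrize(
        "column,value,fragment",
        [
            ("bcva_logmar", 0.4, "20/40"),
            ("iop", 21.5, "IOP"),
            ("cylinder", -3.5, "cylinder"),
            ("cylinder", 3.5, "cylinder"),
            ("signal_strength_macula", 4.0, "signal"),
        ],
    )
    def test_each_rule_fires(self, column, value, fragment):
        frame = make_eye_rows(1, **{column: [value]})
        retained, report = apply_exclusions(cohort_from_frame(frame))
        assert len(retained) == 0
        assert any(fragment in rule for _, _, rule in report.entries)

    def test_bcva_exactly_20_40_retained(self):
        frame = make_eye_rows(1, bcva_logmar=[0.30])
        retained, _ = apply_exclusions(cohort_from_frame(frame))
        assert len(retained) == 1

    def test_compliant_cohort_is_identity(self, toy_frame):
        cohort = cohort_from_frame(toy_frame)
        retained, report = apply_exclusions(cohort)
        pd.testing.assert_frame_equal(retained.frame, cohort.frame)
        assert report.counts_per_rule == {}

    def test_counts_partition_the_input(self):
        frame = make_eye_rows(5)
        frame.loc[1, "iop"] = 30.0
        frame.loc[3, "signal_strength_macula"] = 3.0
        retained, report = apply_exclusions(cohort_from_frame(frame))
        assert report.n_input == 5
        assert report.n_excluded + report.n_retained == report.n_input

    def test_filtering_is_idempotent(self):
        frame = make_eye_rows(4)
        frame.loc[0, "cylinder"] = 3.2
        once, _ = apply_exclusions(cohort_from_frame(frame))
        twice, second_report = apply_exclusions(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        assert not second_report.entries

    def test_missing_optional_field_warns_not_excludes(self):
        frame = make_eye_rows(2)
        frame.loc[0, "cylinder"] = np.nan
        with pytest.warns(UserWarning, match="cylinder"):
            retained, _ = apply_exclusions(cohort_from_frame(frame))
        assert len(retained) == 2


class TestEyeSelection:
    @staticmethod
    def _two_eyed(n_subjects):
        rows = []
        for i in range(n_subjects):
            for eye in ("right", "left"):
                rows.append(make_eye_rows(1, subject_id=[f"P{i}"], eye=[eye]))
        return cohort_from_frame(pd.concat(rows, ignore_index=True))

    def test_one_record_per_subject_and_reproducible(self):
        cohort = self._two_eyed(10)
        first = select_one_eye_per_subject(cohort, seed=5)
        again = select_one_eye_per_subject(cohort, seed=5)
        assert first.frame["subject_id"].is_unique
        pd.testing.assert_frame_equal(first.frame, again.frame)

    def test_single_eye_subject_kept_regardless_of_seed(self):
        frame = make_eye_rows(1, subject_id=["solo"], eye=["left"])
        cohort = cohort_from_frame(frame)
        for seed in (0, 1, 99):
            out = select_one_eye_per_subject(cohort, seed)
            assert out.frame["eye"].tolist() == ["left"]

    def test_different_seeds_may_differ_but_stay_valid(self):
        cohort = self._two_eyed(10)
        a = select_one_eye_per_subject(cohort, seed=1)
        b = select_one_eye_per_subject(cohort, seed=2)
        for sel in (a, b):
            assert len(sel) == 10
            assert sel.frame["subject_id"].is_unique

    def test_row_order_preserved(self):
        cohort = self._two_eyed(6)
        out = select_one_eye_per_subject(cohort, seed=3)
        assert out.frame["subject_id"].tolist() == sorted(
            out.frame["subject_id"], key=lambda s: int(s[1:])
        )


def test_covariate_frame_resolves_model_alias(toy_frame):
    toy_frame["disc_area_corrected"] = 2.1
    cov = covariate_frame(toy_frame, ["age", "corrected_disc_area"])
    assert list(cov.columns) == ["age", "corrected_disc_area"]
    assert (cov["corrected_disc_area"] == 2.1).all()
    with pytest.raises(KeyError):
        covariate_frame(toy_frame, ["not_a_field"])
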