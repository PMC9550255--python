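"""Cohort I/O: loading, exclusion, averaging, binarization, set assignment."""

import logging

import numpy as np
import pandas as pd
import pytest

from bloodclock import (
    InputError,
    assign_sets,
    average_repeated_biometrics,
    binarize_covariates,
    exclude_invalid,
    generate_cohort,
    load_cohort,
    write_cohort,
)
from bloodclock.schema import INDICATOR_ORDER, SchemaError


@pytest.fixture()
def cohort_csv(tmp_path, small_cohort, schema):
    cohort, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path, schema)
    return path, cohort


class TestLoadCohort:
    def test_round_trip(self, cohort_csv, schema):
        path, original = cohort_csv
        loaded, report = load_cohort(path, schema)
        assert report.n_unparseable == 0
        assert loaded["id"].tolist() == original["id"].tolist()
        for col in schema.continuous_predictors:
            np.testing.assert_allclose(loaded[col], original[col], rtol=1e-9)
        assert (loaded["sex"] == original["sex"]).all()

    def test_extra_column_ignored_with_warning(self, cohort_csv, schema, caplog):
        path, _ = cohort_csv
        df = pd.read_csv(path)
        df["mystery"] = 1
        df.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING):
            loaded, report = load_cohort(path, schema)
        assert "mystery" not in loaded.columns
        assert report.ignored_columns == ["mystery"]
        assert any("mystery" in r.message for r in caplog.records)

    def test_na_and_unparseable_cells_become_missing(self, cohort_csv, schema):
        path, _ = cohort_csv
        df = pd.read_csv(path)
        df["glucose"] = df["glucose"].astype(object)
        df.loc[0, "glucose"] = "NA"
        df.loc[1, "glucose"] = "not-a-number"
        df.to_csv(path, index=False)
        loaded, report = load_cohort(path, schema)
        assert loaded["glucose"].iloc[:2].isna().all()
        assert report.unparseable_cells == {"glucose": 1}  # "NA" is missing, not bad
        assert len(loaded) == len(df)  # rows retained until the exclusion stage

    def test_missing_mandatory_column_raises(self, cohort_csv, schema):
        path, _ = cohort_csv
        pd.read_csv(path).drop(columns=["glucose"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="glucose"):
            load_cohort(path, schema)

    def test_empty_file_raises(self, tmp_path, schema):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(InputError):
            load_cohort(path, schema)


class TestExcludeInvalid:
    def test_all_valid_rows_pass_unchanged(self, small_cohort, schema):
        cohort, _ = small_cohort
        clean, log = exclude_invalid(cohort, schema)
        assert len(log) == 0
        pd.testing.assert_frame_equal(clean, cohort.reset_index(drop=True))

    def test_missing_sex_excluded(self, small_cohort, schema):
        cohort, _ = small_cohort
        cohort = cohort.copy()
        cohort.loc[cohort.index[:3], "sex"] = pd.NA
        clean, log = exclude_invalid(cohort, schema)
        assert len(clean) == len(cohort) - 3
        assert (log["reason"] == "missing_sex").sum() == 3

    def test_out_of_range_bmi_excluded(self, small_cohort, schema):
        cohort, _ = small_cohort
        toy = cohort.head(5).copy()
        toy.loc[toy.index[2], "bmi"] = 5.0  # below the schema low of 10
        clean, log = exclude_invalid(toy, schema)
        assert len(clean) == 4
        assert log["reason"].tolist() == ["out_of_range:bmi"]

    def test_missing_predictor_excluded(self, small_cohort, schema):
        cohort, _ = small_cohort
        cohort = cohort.copy()
        cohort.loc[cohort.index[0], "glucose"] = np.nan
        clean, log = exclude_invalid(cohort, schema)
        assert log["reason"].tolist() == ["missing_predictor:glucose"]

    def test_exclusion_is_idempotent(self, small_cohort, schema):
        cohort, _ = small_cohort
        cohort = cohort.copy()
        cohort.loc[cohort.index[:2], "sex"] = pd.NA
        cohort.loc[cohort.index[5], "glucose"] = 9000.0
        once, _ = exclude_invalid(cohort, schema)
        twice, log2 = exclude_invalid(once, schema)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(once, twice)


class TestAverageRepeatedBiometrics:
    def test_mean_single_and_partial_missing(self, schema):
        raw = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "systolic_bp__1": [120.0, 118.0, np.nan],
                "systolic_bp__2": [130.0, np.nan, np.nan],
                "systolic_bp__3": [125.0, 122.0, np.nan],
                "heart_rate__1": [70.0, 72.0, 74.0],
            }
        )
        out = average_repeated_biometrics(raw, schema)
        assert out["systolic_bp"].tolist()[:2] == [125.0, 120.0]
        assert np.isnan(out["systolic_bp"].iloc[2])  # all repeats missing
        assert out["heart_rate"].tolist() == [70.0, 72.0, 74.0]  # single reading
        assert "systolic_bp__1" not in out.columns


class TestBinarizeCovariates:
    def test_indicator_rules(self, schema):
        cohort = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "sex": ["male", "female", "female"],
                "area": ["rural", "urban", "rural"],
                "marital_status": ["widowed", "married", "never_married"],
                "smoking": [1, 0, 0],
                **{item: [0, 3, 1] for item in schema.psych_items},
            }
        )
        out = binarize_covariates(cohort, schema)
        a, b, c = out.iloc[0], out.iloc[1], out.iloc[2]
        assert a["is_married"] == 0 and a["is_widowed"] == 1
        assert b["is_married"] == 1 and b["is_widowed"] == 0
        assert c["is_married"] == 0 and c["is_widowed"] == 0  # reference level
        assert a["rarely_depressed"] == 1  # lowest frequency level
        assert b["restless_sleep_is_rare"] == 0  # most days
        assert c["rarely_happy"] == 0  # level 1 is not "rarely"

    def test_totality_on_generated_cohort(self, small_cohort, schema):
        cohort, _ = small_cohort
        out = binarize_covariates(cohort, schema)
        assert list(out.columns) == ["id", *INDICATOR_ORDER]
        assert out[list(INDICATOR_ORDER)].isin([0, 1]).all().all()
        assert len(out) == len(cohort)

    def test_unknown_level_raises_naming_it(self, schema, small_cohort):
        cohort, _ = small_cohort
        cohort = cohort.copy()
        cohort.loc[cohort.index[0], "marital_status"] = "divorced"
        with pytest.raises(SchemaError, match="divorced"):
            binarize_covariates(cohort, schema)


class TestAssignSets:
    @pytest.fixture()
    def assigned(self, small_cohort, schema):
        cohort, _ = small_cohort
        return cohort, assign_sets(cohort, schema, seed=5)

    def test_partition_is_exhaustive_and_exclusive(self, assigned):
        cohort, assignment = assigned
        labels = assignment.table.set_index("id")["label"]
        assert set(labels.index) == set(cohort["id"])
        assert labels.isin(["train", "test", "discovery"]).all()
        assert sum(assignment.counts().values()) == len(cohort)

    def test_serious_condition_goes_to_discovery(self, assigned, schema):
        cohort, assignment = assigned
        labels = assignment.table.set_index("id")["label"]
        serious = cohort[schema.serious_conditions].sum(axis=1) > 0
        assert (labels.loc[cohort.loc[serious, "id"]] == "discovery").all()
        assert (labels.loc[cohort.loc[~serious, "id"]] != "discovery").all()

    def test_mild_condition_goes_to_test(self, assigned, schema):
        cohort, assignment = assigned
        labels = assignment.table.set_index("id")["label"]
        serious = cohort[schema.serious_conditions].sum(axis=1) > 0
        mild_only = (cohort[schema.mild_conditions].sum(axis=1) > 0) & ~serious
        assert (labels.loc[cohort.loc[mild_only, "id"]] == "test").all()

    def test_healthy_split_is_seeded_and_deterministic(self, small_cohort, schema):
        cohort, _ = small_cohort
        a = assign_sets(cohort, schema, seed=5).table
        b = assign_sets(cohort, schema, seed=5).table
        c = assign_sets(cohort, schema, seed=6).table
        pd.testing.assert_frame_equal(a, b)
        assert not a["label"].equals(c["label"])

    def test_excluded_rows_carry_their_reason(self, small_cohort, schema):
        cohort, _ = small_cohort
        cohort = cohort.copy()
        cohort.loc[cohort.index[0], "sex"] = pd.NA
        clean, log = exclude_invalid(cohort, schema)
        assignment = assign_sets(clean, schema, seed=1, excluded=log)
        row = assignment.table[assignment.table["label"] == "excluded"]
        assert len(row) == 1 and row["reason"].iloc[0] == "missing_sex"
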