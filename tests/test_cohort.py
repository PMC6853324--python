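"""Cohort I/O, exclusion filters and covariate standardization."""

import numpy as np
import pandas as pd
import pytest

from cd4cvl.cohort import (
    CohortError,
    CohortTable,
    apply_exclusions,
    read_cohort,
    standardize_covariates,
    write_cohort,
)
from cd4cvl.simulate import SyntheticConfig, generate_cohort


class TestReadWrite:
    def test_reads_toy_file_preserving_missing_cells(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "patient_id,time_on_art,cd4,viral_load,first_line,"
            "sex,age,baseline_cd4,baseline_log_vl,in_care\n"
            "P1,0,100,50000,1,1,34,100,4.7,1\n"
            "P1,0.5,150,,1,1,34,100,4.7,1\n"
            "P2,0,80,120000,1,0,41,80,5.1,1\n"
        )
        cohort = read_cohort(path)
        assert cohort.n_visits == 3
        assert cohort.visits["viral_load"].isna().sum() == 1
        assert cohort.n_patients == 2

    def test_missing_required_column_is_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,time_on_art,viral_load\nP1,0,500\n")
        with pytest.raises(CohortError, match="cd4"):
            read_cohort(path)

    def test_duplicate_patient_time_rejected(self):
        visits = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "time_on_art": [0.0, 0.0],
                "cd4": [100.0, 110.0],
                "viral_load": [500.0, 600.0],
                "first_line": [True, True],
            }
        )
        baselines = pd.DataFrame(
            {
                "patient_id": ["A"],
                "sex": [1.0],
                "age": [30.0],
                "baseline_cd4": [100.0],
                "baseline_log_vl": [4.0],
                "in_care": [1],
            }
        )
        with pytest.raises(CohortError, match="duplicate"):
            CohortTable(visits, baselines).validate()

    def test_dialect_maps_column_names(self, tmp_path):
        path = tmp_path / "dialect.csv"
        path.write_text(
            "id,yrs,cd4_cells,vl,line1,sex,age,baseline_cd4,baseline_log_vl,in_care\n"
            "P1,0,90,1000,1,1,30,90,5.0,1\nP1,0.5,120,800,1,1,30,90,5.0,1\n"
        )
        cohort = read_cohort(
            path,
            dialect={
                "patient_id": "id",
                "time_on_art": "yrs",
                "cd4": "cd4_cells",
                "viral_load": "vl",
                "first_line": "line1",
            },
        )
        assert cohort.n_visits == 2

    def test_synthetic_round_trip_preserves_missingness(self, tmp_path):
        cfg = SyntheticConfig(n_patients=25, seed=5)
        cohort, _ = generate_cohort(cfg)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        v0 = cohort.visits.reset_index(drop=True)
        v1 = back.visits.reset_index(drop=True)
        v1["patient_id"] = v1["patient_id"].astype(int)
        pd.testing.assert_frame_equal(v0, v1, check_dtype=False)
        b0 = cohort.baselines.reset_index(drop=True)
        b1 = back.baselines.reset_index(drop=True)
        b1["patient_id"] = b1["patient_id"].astype(int)
        pd.testing.assert_frame_equal(b0, b1, check_dtype=False)


class TestExclusions:
    def test_baseline_only_patient_excluded(self, toy_cohort):
        out, report = apply_exclusions(toy_cohort, outcome="slope")
        assert "B" not in set(out.baselines["patient_id"])
        assert report.excluded["baseline-only"] == 1

    def test_high_baseline_cd4_excluded_only_for_asymptote(self, toy_cohort):
        slope, _ = apply_exclusions(toy_cohort, outcome="slope")
        assert "C" in set(slope.baselines["patient_id"])
        asym, report = apply_exclusions(toy_cohort, outcome="asymptote")
        assert "C" not in set(asym.baselines["patient_id"])
        assert report.excluded["baseline-cd4>=500"] == 1

    def test_second_line_visits_removed(self, toy_cohort):
        out, report = apply_exclusions(toy_cohort, outcome="slope")
        c_visits = out.visits[out.visits["patient_id"] == "C"]
        assert len(c_visits) == 3
        assert report.n_second_line_visits_removed == 2

    def test_counts_partition_input(self, toy_cohort):
        _, report = apply_exclusions(toy_cohort, outcome="asymptote")
        assert report.n_input_patients == report.n_retained_patients + sum(
            report.excluded.values()
        )

    def test_empty_cohort_after_exclusions_errors(self, toy_cohort):
        only_b = CohortTable(
            toy_cohort.visits[toy_cohort.visits["patient_id"] == "B"],
            toy_cohort.baselines[toy_cohort.baselines["patient_id"] == "B"],
        )
        with pytest.raises(CohortError):
            apply_exclusions(only_b, outcome="slope")


class TestStandardization:
    def test_zscores_match_closed_form_sample_sd(self):
        visits = pd.DataFrame(
            {
                "patient_id": list("XYZ"),
                "time_on_art": [0.0, 0.0, 0.0],
                "cd4": [1.0, 2.0, 3.0],
                "viral_load": [500.0] * 3,
                "first_line": [True] * 3,
            }
        )
        baselines = pd.DataFrame(
            {
                "patient_id": list("XYZ"),
                "sex": [0.0, 1.0, 1.0],
                "age": [1.0, 2.0, 3.0],
                "baseline_cd4": [10.0, 20.0, 30.0],
                "baseline_log_vl": [4.0, 5.0, 6.0],
                "in_care": [1, 1, 1],
            }
        )
        out, info = standardize_covariates(CohortTable(visits, baselines))
        np.testing.assert_allclose(out.baselines["age"], [-1.0, 0.0, 1.0])
        mean, sd = info.params["age"]
        assert (mean, sd) == (2.0, 1.0)
        # population-sd convention is available through ddof
        out_pop, _ = standardize_covariates(CohortTable(visits, baselines), ddof=0)
        np.testing.assert_allclose(
            out_pop.baselines["age"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_time_on_art_untouched(self, toy_cohort):
        excl, _ = apply_exclusions(toy_cohort, outcome="slope")
        out, _ = standardize_covariates(excl)
        pd.testing.assert_series_equal(out.visits["time_on_art"], excl.visits["time_on_art"])

    def test_standardized_mean_zero_sd_one(self):
        cfg = SyntheticConfig(n_patients=200, seed=8)
        cohort, _ = generate_cohort(cfg)
        excl, _ = apply_exclusions(cohort, outcome="slope")
        out, _ = standardize_covariates(excl)
        for name in ("age", "baseline_cd4", "baseline_log_vl"):
            vals = out.baselines[name].dropna()
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=1) - 1.0) < 1e-10

    def test_zero_variance_covariate_errors(self):
        visits = pd.DataFrame(
            {
                "patient_id": ["X", "Y"],
                "time_on_art": [0.0, 0.0],
                "cd4": [1.0, 2.0],
                "viral_load": [500.0, 600.0],
                "first_line": [True, True],
            }
        )
        baselines = pd.DataFrame(
            {
                "patient_id": ["X", "Y"],
                "sex": [0.0, 1.0],
                "age": [30.0, 30.0],
                "baseline_cd4": [10.0, 20.0],
                "baseline_log_vl": [4.0, 5.0],
                "in_care": [1, 1],
            }
        )
        with pytest.raises(CohortError, match="zero variance"):
            standardize_covariates(CohortTable(visits, baselines))
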