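"""Cohort containers, validation, and round-trip file I/O."""

import dataclasses

import pytest

from radstox.cohort import (
    GradeObservation,
    Patient,
    ToxicityTrajectory,
    TrialCohort,
    VisitSchedule,
    analysis_populations,
    read_cohort,
    write_cohort,
)
from radstox.exceptions import CohortValidationError, SchemaError
from radstox.simulate import SimulationConfig, simulate_cohort


def _patient(pid="A", stratum="standard", arm="no_bolus", **kw):
    base = dict(
        patient_id=pid,
        risk_stratum=stratum,
        arm=arm,
        bmi_stratum="lt30",
        age_years=50.0,
        diabetes=False,
        smoking_ever=False,
        rt_technique="ct_planned",
        followup_years=5.0,
    )
    base.update(kw)
    return Patient(**base)


class TestDomainTypes:
    @pytest.mark.parametrize("grade", [-1, 5, 2.5])
    def test_out_of_range_grade_rejected(self, grade):
        with pytest.raises(ValueError):
            GradeObservation(week=1.0, grade=grade)

    def test_nonpositive_week_rejected(self):
        with pytest.raises(ValueError):
            GradeObservation(week=0.0, grade=1)

    def test_unsorted_or_duplicate_weeks_rejected(self):
        obs = (GradeObservation(2.0, 1), GradeObservation(1.0, 1))
        with pytest.raises(CohortValidationError):
            ToxicityTrajectory("A", obs)
        obs = (GradeObservation(1.0, 1), GradeObservation(1.0, 2))
        with pytest.raises(CohortValidationError):
            ToxicityTrajectory("A", obs)

    def test_post_treatment_must_follow_on_treatment(self):
        obs = (
            GradeObservation(1.0, 1, "post_treatment"),
            GradeObservation(2.0, 1, "on_treatment"),
        )
        with pytest.raises(CohortValidationError):
            ToxicityTrajectory("A", obs)

    def test_bolus_stop_requires_grade3_at_or_before(self):
        obs = (GradeObservation(1.0, 2), GradeObservation(2.0, 3))
        ToxicityTrajectory("A", obs, bolus_stopped_week=2.0)  # fine
        with pytest.raises(CohortValidationError):
            ToxicityTrajectory("A", obs, bolus_stopped_week=1.0)

    @pytest.mark.parametrize(
        "stratum,arm", [("standard", "daily"), ("high", "no_bolus")]
    )
    def test_stratum_arm_menu_is_enforced(self, stratum, arm):
        with pytest.raises(CohortValidationError):
            _patient(stratum=stratum, arm=arm)

    def test_schedule_weeks_must_increase(self):
        with pytest.raises(ValueError):
            VisitSchedule(on_treatment_weeks=(1.0, 1.0))
        with pytest.raises(ValueError):
            VisitSchedule(on_treatment_weeks=(1.0, 7.0), post_treatment_weeks=(6.6,))

    def test_trajectory_for_unknown_patient_rejected(self):
        traj = ToxicityTrajectory("B", (GradeObservation(1.0, 1),))
        with pytest.raises(CohortValidationError):
            TrialCohort(patients={"A": _patient()}, trajectories={"B": traj})


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_read_identity(self, tmp_path, seed):
        cohort = simulate_cohort(SimulationConfig(n_standard=8, n_high=6), seed)
        p, t = write_cohort(cohort, tmp_path)
        back = read_cohort(p, t)
        assert back.patients == cohort.patients
        assert back.trajectories == cohort.trajectories

    def test_optional_fields_round_trip_as_blanks(self, tmp_path):
        cohort = simulate_cohort(
            SimulationConfig(n_standard=6, n_high=4, local_control_5yr_standard=1.0,
                             local_control_5yr_high=1.0),
            seed=5,
        )
        assert all(
            p.local_failure_time_years is None for p in cohort.patients.values()
        )
        p, t = write_cohort(cohort, tmp_path)
        assert read_cohort(p, t).patients == cohort.patients

    def test_fixture_writes_51_patient_rows(self, tmp_path, fixture_cohort):
        p, _ = write_cohort(fixture_cohort, tmp_path)
        rows = p.read_text().strip().splitlines()
        assert len(rows) == 52  # header + 51 patients


class TestReadErrors:
    def _write(self, tmp_path, patients_rows, toxicity_rows):
        pfile = tmp_path / "patients.csv"
        tfile = tmp_path / "toxicity.csv"
        header_p = (
            "patient_id,risk_stratum,arm,bmi_stratum,age_years,diabetes,"
            "smoking_ever,rt_technique,local_failure,local_failure_time_years,"
            "followup_years,metastasis_at_or_before_rt"
        )
        header_t = "patient_id,week,grade,visit_kind,bolus_stopped"
        pfile.write_text("\n".join([header_p] + patients_rows) + "\n")
        tfile.write_text("\n".join([header_t] + toxicity_rows) + "\n")
        return pfile, tfile

    def test_empty_toxicity_file_is_validation_error(self, tmp_path):
        p, t = self._write(
            tmp_path,
            ["A,standard,no_bolus,lt30,50,0,0,ct_planned,0,,5.0,0"],
            [],
        )
        with pytest.raises(CohortValidationError, match="A"):
            read_cohort(p, t)

    def test_grade_five_names_file_line_and_field(self, tmp_path):
        p, t = self._write(
            tmp_path,
            ["A,standard,no_bolus,lt30,50,0,0,ct_planned,0,,5.0,0"],
            ["A,1.0,5,on_treatment,0"],
        )
        with pytest.raises(SchemaError) as err:
            read_cohort(p, t)
        assert err.value.field == "grade"
        assert err.value.line == 2

    def test_bad_arm_is_schema_error(self, tmp_path):
        p, t = self._write(
            tmp_path,
            ["A,standard,boost,lt30,50,0,0,ct_planned,0,,5.0,0"],
            ["A,1.0,1,on_treatment,0"],
        )
        with pytest.raises(SchemaError) as err:
            read_cohort(p, t)
        assert err.value.field == "arm"


class TestAnalysisPopulations:
    def test_fixture_population_sizes(self, fixture_cohort):
        tox, onc = analysis_populations(fixture_cohort)
        assert len(tox) == 51
        assert len(onc) == 48

    def test_idempotent_subsets(self, fixture_cohort):
        tox, onc = analysis_populations(fixture_cohort)
        tox2, onc2 = analysis_populations(fixture_cohort)
        assert (tox, onc) == (tox2, onc2)
        assert onc <= tox <= set(fixture_cohort.patients)

    def test_no_metastasis_means_equal_sets(self):
        patients = {p.patient_id: p for p in [_patient("A"), _patient("B")]}
        trajs = {
            pid: ToxicityTrajectory(pid, (GradeObservation(1.0, 1),))
            for pid in patients
        }
        tox, onc = analysis_populations(TrialCohort(patients, trajs))
        assert tox == onc == {"A", "B"}

    def test_metastatic_flags_excluded_from_oncologic(self):
        patients = {}
        trajs = {}
        for k in range(5):
            pid = f"P{k}"
            patients[pid] = _patient(pid, metastasis_at_or_before_rt=k < 2)
            trajs[pid] = ToxicityTrajectory(pid, (GradeObservation(1.0, 1),))
        tox, onc = analysis_populations(TrialCohort(patients, trajs))
        assert len(tox) == 5
        assert len(onc) == 3

    def test_patient_without_observations_excluded_from_toxicity(self):
        patients = {p.patient_id: p for p in [_patient("A"), _patient("B")]}
        trajs = {"A": ToxicityTrajectory("A", (GradeObservation(1.0, 1),))}
        tox, _ = analysis_populations(TrialCohort(patients, trajs))
        assert tox == {"A"}
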