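"""Synthetic-trial generator: randomization, trajectories, calibration."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

from radstox.calibrate import (
    INCIDENCE_TARGETS,
    calibrate_subgroup,
    default_progression,
    reach_probability,
)
from radstox.cohort import analysis_populations
from radstox.incidence import first_exceedance_week, landmark_counts
from radstox.simulate import (
    SimulationConfig,
    config_from_yaml,
    config_to_yaml,
    fixture_cohort_from_printed_counts,
    simulate_cohort,
    simulate_oncologic,
    simulate_scores_two_group,
    simulate_toxicity,
    stratified_randomize,
)


class TestStratifiedRandomize:
    def test_full_blocks_balance_exactly(self):
        patients = [(f"P{k}", "standard", "lt30" if k < 10 else "ge30")
                    for k in range(20)]
        cfg = SimulationConfig(block_size=2)
        assignment = stratified_randomize(patients, cfg, np.random.default_rng(0))
        for bmi in ("lt30", "ge30"):
            arms = Counter(
                assignment[pid] for pid, _, b in patients if b == bmi
            )
            assert arms == {"no_bolus": 5, "alternate": 5}

    def test_deterministic_under_fixed_seed(self):
        patients = [(f"P{k}", "high", "lt30") for k in range(9)]
        cfg = SimulationConfig()
        a1 = stratified_randomize(patients, cfg, np.random.default_rng(7))
        a2 = stratified_randomize(patients, cfg, np.random.default_rng(7))
        assert a1 == a2

    def test_arm_menu_respected_per_stratum(self):
        patients = [(f"S{k}", "standard", "lt30") for k in range(10)]
        patients += [(f"H{k}", "high", "ge30") for k in range(10)]
        cfg = SimulationConfig()
        assignment = stratified_randomize(patients, cfg, np.random.default_rng(1))
        assert all(assignment[f"S{k}"] in ("no_bolus", "alternate") for k in range(10))
        assert all(assignment[f"H{k}"] in ("alternate", "daily") for k in range(10))

    @pytest.mark.parametrize("block", [2, 4])
    def test_within_cell_imbalance_bounded_by_block_size(self, block):
        cfg = SimulationConfig(block_size=block)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 40))
            patients = [(f"P{k}", "standard", "lt30") for k in range(n)]
            arms = Counter(stratified_randomize(patients, cfg, rng).values())
            assert abs(arms["no_bolus"] - arms["alternate"]) <= block


class TestSimulateToxicity:
    def _config(self, probs):
        prog = {
            sub: {"on": probs, "post": (0.0, 0.0, probs[2])}
            for sub in ("sr_no_bolus", "sr_alternate", "hr_alternate", "hr_daily")
        }
        return SimulationConfig(progression=prog)

    def test_zero_probabilities_give_all_zero_grades(self):
        cfg = self._config((0.0, 0.0, 0.0))
        traj = simulate_toxicity(
            "hr_daily", "daily", cfg, np.random.default_rng(0), "A"
        )
        assert traj.grades == (0,) * 8
        assert traj.bolus_stopped_week is None

    def test_certain_progression_is_forced_path_with_bolus_stop(self):
        cfg = self._config((1.0, 1.0, 1.0))
        traj = simulate_toxicity(
            "hr_daily", "daily", cfg, np.random.default_rng(0), "A"
        )
        assert traj.grades[:3] == (1, 2, 3)
        assert traj.bolus_stopped_week == 3.0
        assert max(traj.grades) == 3  # no grade-4 step is modeled by default

    def test_no_bolus_arm_never_stops_bolus(self):
        cfg = self._config((1.0, 1.0, 1.0))
        traj = simulate_toxicity(
            "sr_no_bolus", "no_bolus", cfg, np.random.default_rng(0), "A"
        )
        assert traj.bolus_stopped_week is None

    def test_grades_monotone_nondecreasing(self):
        cfg = SimulationConfig()
        for seed in range(20):
            traj = simulate_toxicity(
                "hr_daily", "daily", cfg, np.random.default_rng(seed), "A"
            )
            assert all(b >= a for a, b in zip(traj.grades, traj.grades[1:]))


class TestSimulateOncologic:
    def test_perfect_control_never_fails(self):
        cfg = SimulationConfig(local_control_5yr_standard=1.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            out = simulate_oncologic("standard", cfg, rng)
            assert not out["local_failure"]

    def test_failure_fraction_matches_closed_form(self):
        # exp(-5 lambda) = 0.9: the 5-year failure probability is 10%
        cfg = SimulationConfig(
            local_control_5yr_high=0.9,
            followup_median_years=50.0,  # effectively no censoring before 5y
            followup_half_range_years=0.1,
        )
        rng = np.random.default_rng(1)
        fails = 0
        n = 10_000
        for _ in range(n):
            out = simulate_oncologic("high", cfg, rng)
            t = out["local_failure_time_years"]
            fails += out["local_failure"] and t is not None and t <= 5.0
        assert fails / n == pytest.approx(0.10, abs=0.01)

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig()
        a = simulate_oncologic("high", cfg, np.random.default_rng(3))
        b = simulate_oncologic("high", cfg, np.random.default_rng(3))
        assert a == b


class TestCalibration:
    def test_reach_probability_against_monte_carlo(self):
        p_on, p_post = (0.8, 0.3, 0.2), (0.0, 0.0, 0.2)
        exact = reach_probability(p_on, p_post, 6, 2, 2)
        rng = np.random.default_rng(0)
        hits = 0
        n = 20_000
        for _ in range(n):
            grade = 0
            for phase, k in ((p_on, 6), (p_post, 2)):
                for _v in range(k):
                    if grade < 3 and rng.random() < phase[grade]:
                        grade += 1
            hits += grade >= 2
        assert hits / n == pytest.approx(exact, abs=0.01)

    def test_bisection_hits_targets_exactly(self):
        for sub, (g2, g3) in INCIDENCE_TARGETS.items():
            cols = calibrate_subgroup(g2, g3)
            got_g2 = reach_probability(
                (cols["on"][0], cols["on"][1], 0.0), (0.0, 0.0, 0.0), 6, 2, 2
            )
            got_g3 = reach_probability(cols["on"], cols["post"], 6, 2, 3)
            assert got_g2 == pytest.approx(g2, abs=1e-9)
            assert got_g3 == pytest.approx(g3, abs=1e-9)

    def test_zero_g3_target_gives_zero_step_probability(self):
        assert default_progression()["sr_no_bolus"]["on"][2] == 0.0
        assert default_progression()["sr_alternate"]["post"][2] == 0.0


class TestSimulateCohort:
    def test_deterministic_and_seed_sensitive(self):
        cfg = SimulationConfig(n_standard=10, n_high=8)
        a = simulate_cohort(cfg, 5)
        b = simulate_cohort(cfg, 5)
        c = simulate_cohort(cfg, 6)
        assert a.patients == b.patients and a.trajectories == b.trajectories
        assert a.trajectories != c.trajectories

    def test_adding_patients_preserves_existing_trajectories(self):
        small = simulate_cohort(SimulationConfig(n_standard=10, n_high=5), 9)
        large = simulate_cohort(SimulationConfig(n_standard=10, n_high=8), 9)
        for pid in small.trajectories:
            assert large.trajectories[pid] == small.trajectories[pid]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(n_standard=0, n_high=0), 0)

    def test_strata_sizes_and_arm_menus(self, small_simulated_cohort):
        c = small_simulated_cohort
        strata = Counter(p.risk_stratum for p in c.patients.values())
        assert strata == {"standard": 32, "high": 19}
        for p in c.patients.values():
            if p.risk_stratum == "standard":
                assert p.arm in ("no_bolus", "alternate")
            else:
                assert p.arm in ("alternate", "daily")


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_standard=12, obesity_prob=0.4).resolved()
        path = config_to_yaml(cfg, tmp_path / "config.yaml")
        back = config_from_yaml(path)
        assert back == cfg

    def test_unknown_key_is_named(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("n_standard: 5\nwarp_factor: 9\n")
        with pytest.raises(ValueError, match="warp_factor"):
            config_from_yaml(path)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="obesity_prob"):
            SimulationConfig(obesity_prob=1.5)


class TestFixtureCohort:
    def test_fifty_one_patients_with_printed_max_grades(self, fixture_cohort):
        assert len(fixture_cohort) == 51
        mg = Counter(t.max_grade for t in fixture_cohort.trajectories.values())
        assert mg == {1: 28, 2: 15, 3: 8}

    def test_everyone_reaches_grade_one(self, fixture_cohort):
        assert all(t.max_grade >= 1 for t in fixture_cohort.trajectories.values())

    def test_five_post_treatment_grade3_onsets(self, fixture_cohort):
        onsets = [
            first_exceedance_week(t, 3)
            for t in fixture_cohort.trajectories.values()
        ]
        post = [
            w for w in onsets
            if w is not None and w > fixture_cohort.schedule.end_of_treatment_week
        ]
        assert len(post) == 5
        assert sum(w is not None for w in onsets) == 8

    def test_three_bolus_discontinuations_in_last_treatment_week(self, fixture_cohort):
        stops = [
            (p.arm, t.bolus_stopped_week)
            for p, t in zip(
                fixture_cohort.patients.values(),
                fixture_cohort.trajectories.values(),
            )
            if t.bolus_stopped_week is not None
        ]
        assert len(stops) == 3
        assert all(w == 5.6 for _, w in stops)
        assert Counter(a for a, _ in stops) == {"alternate": 1, "daily": 2}

    def test_oncologic_population_is_48(self, fixture_cohort):
        tox, onc = analysis_populations(fixture_cohort)
        assert (len(tox), len(onc)) == (51, 48)

    def test_one_local_failure_per_arm(self, fixture_cohort):
        fails = Counter(
            p.subgroup for p in fixture_cohort.patients.values() if p.local_failure
        )
        assert fails == {
            "sr_no_bolus": 1, "sr_alternate": 1, "hr_alternate": 1, "hr_daily": 1
        }


class TestScoresGenerator:
    def test_two_group_scores_recover_placement_probability(self, rng):
        ref, trt = simulate_scores_two_group(20_000, 0.75, rng)
        emp = np.mean(ref[:, None] < trt[None, :])
        assert emp == pytest.approx(0.75, abs=0.01)
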