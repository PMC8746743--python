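"""Synthetic interval-based incentivized Stroop generator."""

import numpy as np
import pandas as pd
import pytest

from rrddm.ddm import DDMParams, ddm_expected_performance
from rrddm.reward_rate import IncentiveWeights
from rrddm.task import (
    Condition,
    ExperimentDesign,
    SubjectProfile,
    build_profile,
    generate_experiment,
    summarize_behavior,
)


def flat_profile(params: DDMParams, design: ExperimentDesign, subject=0) -> SubjectProfile:
    """Same DDM parameters in every condition and congruency."""
    cond_params = {"congruent": params, "incongruent": params}
    return SubjectProfile(
        subject=subject,
        params={(c.reward_level, c.penalty_level): dict(cond_params) for c in design.conditions},
        ndt=params.ndt,
    )


WEIGHTS_2x2 = {
    (1, 1): IncentiveWeights(9, 13), (1, 10): IncentiveWeights(9, 40),
    (10, 1): IncentiveWeights(20, 13), (10, 10): IncentiveWeights(20, 40),
}


class TestDesign:
    def test_study_condition_sets(self):
        assert len(ExperimentDesign(study=1).conditions) == 4
        assert len(ExperimentDesign(study=2).conditions) == 9
        assert ExperimentDesign(study=1).n_intervals == 80
        assert ExperimentDesign(study=2).n_intervals == 72

    @pytest.mark.parametrize("kwargs", [
        dict(study=3), dict(interval_duration_range=(5, 12)),
        dict(congruent_fraction=0.0), dict(intervals_per_condition=0),
        dict(boundary_policy="extend"),
    ])
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentDesign(**kwargs)


class TestBuildProfile:
    def test_equal_weights_give_identical_conditions(self):
        w = {k: IncentiveWeights(10, 10) for k in WEIGHTS_2x2}
        prof = build_profile(w)
        params = [prof.params[k]["congruent"] for k in w]
        assert all(p == params[0] for p in params)

    def test_higher_reward_raises_congruent_drift(self):
        prof = build_profile(WEIGHTS_2x2)
        assert prof.params[(10, 1)]["congruent"].v > prof.params[(1, 1)]["congruent"].v

    def test_zero_offsets_share_parameters_across_congruency(self):
        prof = build_profile(WEIGHTS_2x2, congruence_offsets=(0.0, 0.0))
        for pair in prof.params.values():
            assert pair["congruent"] == pair["incongruent"]

    def test_congruence_offsets_respect_interference_direction(self):
        prof = build_profile(WEIGHTS_2x2, congruence_offsets=(0.3, 0.1))
        for pair in prof.params.values():
            assert pair["incongruent"].v < pair["congruent"].v
            assert pair["incongruent"].a > pair["congruent"].a

    def test_negative_offsets_rejected(self):
        with pytest.raises(ValueError, match="offsets"):
            build_profile(WEIGHTS_2x2, congruence_offsets=(-0.1, 0.0))

    def test_facilitation_profile_rejected(self):
        good = DDMParams(v=1.0, a=1.0)
        fast = DDMParams(v=2.0, a=1.0)
        with pytest.raises(ValueError, match="incongruent"):
            SubjectProfile(subject=0, params={(1, 1): {"congruent": good, "incongruent": fast}}, ndt=0.0)


@pytest.fixture(scope="module")
def small_run():
    design = ExperimentDesign(study=1, intervals_per_condition=5)
    prof = build_profile(WEIGHTS_2x2, subject=0)
    return design, generate_experiment(design, [prof], rng_seed=11)

class TestGenerateExperiment:
    def test_deterministic_under_seed(self):
        design = ExperimentDesign(study=1, intervals_per_condition=2)
        prof = build_profile(WEIGHTS_2x2)
        t1, i1 = generate_experiment(design, [prof], rng_seed=99)
        t2, i2 = generate_experiment(design, [prof], rng_seed=99)
        assert t1.to_csv() == t2.to_csv()
        assert i1.to_csv() == i2.to_csv()

    def test_trials_fit_within_interval_duration(self, small_run):
        _, (trials, intervals) = small_run
        rt_sums = trials.groupby("interval")["rt"].sum()
        durations = intervals.set_index("interval")["duration"]
        assert (rt_sums <= durations.loc[rt_sums.index] + 1e-9).all()

    def test_earnings_ledger_is_exact(self, small_run):
        _, (trials, intervals) = small_run
        expected = (intervals["condition_reward"] * intervals["n_correct"]
                    - intervals["condition_penalty"] * intervals["n_error"])
        pd.testing.assert_series_equal(intervals["earnings"], expected, check_names=False)
        assert trials["earnings"].sum() == intervals["earnings"].sum()

    def test_correct_per_second_definition(self, small_run):
        _, (_, intervals) = small_run
        np.testing.assert_allclose(
            intervals["correct_per_second"], intervals["n_correct"] / intervals["duration"]
        )

    def test_trial_count_matches_renewal_expectation(self):
        # mean RT ~0.8 s in a ~10 s interval -> about 12 trials per interval
        params = DDMParams(v=1.0, a=2.0, ndt=0.8 - ddm_expected_performance(DDMParams(v=1.0, a=2.0)).dt)
        design = ExperimentDesign(study=1, intervals_per_condition=250)
        prof = flat_profile(params, design)
        _, intervals = generate_experiment(design, [prof], rng_seed=17)
        assert len(intervals) == 1000
        assert intervals["n_trials"].mean() == pytest.approx(10.0 / 0.8, abs=1.0)

    def test_congruence_is_iid_not_exactly_balanced(self, small_run):
        _, (trials, _) = small_run
        frac = trials["congruent"].mean()
        assert 0.45 < frac < 0.55
        per_interval = trials.groupby("interval")["congruent"].mean()
        assert per_interval.nunique() > 1  # proportion varies across intervals

    def test_omission_policy_records_unscored_tail(self):
        design = ExperimentDesign(study=1, intervals_per_condition=2,
                                  boundary_policy="truncate_as_omission")
        prof = build_profile(WEIGHTS_2x2)
        trials, intervals = generate_experiment(design, [prof], rng_seed=5)
        omitted = trials[trials["correct"].isna()]
        assert len(omitted) == intervals["n_omitted"].sum() > 0
        assert (omitted["earnings"] == 0).all()
        rt_sums = trials.groupby("interval")["rt"].sum()
        durations = intervals.set_index("interval")["duration"]
        np.testing.assert_allclose(rt_sums, durations.loc[rt_sums.index])

    def test_missing_condition_is_configuration_error(self):
        design = ExperimentDesign(study=1)
        partial = {k: WEIGHTS_2x2[k] for k in [(1, 1), (1, 10)]}
        prof = build_profile(partial)
        with pytest.raises(ValueError, match="lacks conditions"):
            generate_experiment(design, [prof], rng_seed=0)


class TestSummaries:
    def test_toy_interval_arithmetic(self):
        trials = pd.DataFrame({
            "subject": 0, "interval": 0, "condition_reward": 10, "condition_penalty": 1,
            "congruent": [1, 0, 1, 0], "rt": [0.5, 0.7, 0.6, 0.8], "correct": [1, 1, 0, 1],
        })
        intervals = pd.DataFrame({
            "subject": [0], "interval": [0], "condition_reward": [10],
            "condition_penalty": [1], "duration": [10.0], "n_correct": [8],
            "correct_per_second": [0.8],
        })
        s = summarize_behavior(trials, intervals, n_boot=50)
        row = s["by_condition"].iloc[0]
        assert row["correct_per_second"] == pytest.approx(0.8)
        assert row["accuracy"] == pytest.approx(0.75)
        assert row["mean_rt_correct"] == pytest.approx((0.5 + 0.7 + 0.8) / 3)

    def test_incentive_contrasts_follow_the_generating_profile(self):
        design = ExperimentDesign(study=1, intervals_per_condition=10)
        profs = [build_profile(WEIGHTS_2x2, subject=s) for s in range(3)]
        trials, intervals = generate_experiment(design, profs, rng_seed=8)
        s = summarize_behavior(trials, intervals, n_boot=200, rng_seed=1)
        con = s["contrasts"].set_index(["axis", "measure"])["mean_diff"]
        assert con[("reward", "mean_rt_correct")] < 0
        assert con[("reward", "correct_per_second")] > 0
        assert con[("penalty", "accuracy")] > 0
        assert con[("penalty", "correct_per_second")] < 0

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            summarize_behavior(pd.DataFrame(), pd.DataFrame())
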