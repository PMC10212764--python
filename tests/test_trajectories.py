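"""Trajectory regression, cluster bootstrap, permutation ANOVA, curves."""

import numpy as np
import pandas as pd
import pytest

from metabotrace import (
    adjusted_pair,
    fit_trajectory,
    interpolate_to_age,
    mean_anova,
    slope_anova,
    trajectory_curves,
)
from metabotrace.trajectories import _cluster_resample, _subject_row_groups
from conftest import two_axis_config
from metabotrace import generate_cohort, CohortDesign, GeneratorConfig, MeasureSpec


def make_cohort(n_subjects, slope, noise, seed=0, intercept=0.0, icc=0.5,
                baseline=(24.0, 39.0)):
    """Simple one-group longitudinal cohort with known slope (SD/decade)."""
    rng = np.random.default_rng(seed)
    age0 = rng.uniform(*baseline, n_subjects)
    u = rng.normal(0, np.sqrt(icc) * noise, n_subjects)
    rows = []
    for v, off in enumerate((0.0, 6.0, 10.0)):
        age = age0 + off
        y = intercept + slope * (age - 24.0) / 10.0 + u + rng.normal(
            0, np.sqrt(1 - icc) * noise, n_subjects
        )
        rows.append(
            pd.DataFrame(
                {
                    "cohort_id": "c",
                    "subject_id": [f"s{i:04d}" for i in range(n_subjects)],
                    "visit_id": f"v{v+1}",
                    "age": age,
                    "sex": 0,
                    "birth_year": 2001 - np.floor(age0).astype(int),
                    "y": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def one_group_labels(cohort, label="g"):
    return {s: label for s in cohort["subject_id"].unique()}


class TestInterpolation:
    def test_birth_cohort_weights_are_seven_and_eight_fifteenths(self):
        w_early, w_late, _ = interpolate_to_age(None, None, 31.0, 46.0, 39.0)
        assert w_early == pytest.approx(7 / 15, abs=1e-15)
        assert w_late == pytest.approx(8 / 15, abs=1e-15)
        assert (round(w_early, 2), round(w_late, 2)) == (0.47, 0.53)

    def test_boundary_and_midpoint_weights(self):
        w_e, w_l, x = interpolate_to_age(np.array([2.0]), np.array([8.0]),
                                         31.0, 46.0, 31.0)
        assert (w_e, w_l) == (1.0, 0.0)
        assert x[0] == 2.0
        w_e, w_l, x = interpolate_to_age(np.array([2.0]), np.array([8.0]),
                                         30.0, 40.0, 35.0)
        assert (w_e, w_l) == (0.5, 0.5)
        assert x[0] == 5.0

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="outside"):
            interpolate_to_age(None, None, 31.0, 46.0, 50.0)

    def test_missing_propagates(self):
        _, _, x = interpolate_to_age(np.array([np.nan, 1.0]),
                                     np.array([2.0, 3.0]), 31.0, 46.0, 39.0)
        assert np.isnan(x[0]) and np.isfinite(x[1])


class TestFitTrajectory:
    def test_noiseless_slope_exact_with_degenerate_ci(self):
        cohort = make_cohort(40, slope=1.0, noise=0.0)
        fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g",
                             standardize_measure=False, n_boot=300, seed=0)
        assert fit.beta_age == pytest.approx(1.0, abs=1e-9)
        assert fit.ci_high - fit.ci_low < 1e-9
        assert fit.n_observations == 3 * fit.n_subjects

    def test_birth_year_recentering_invariance(self):
        cohort = make_cohort(60, slope=0.4, noise=0.8, seed=3)
        shifted = cohort.copy()
        shifted["birth_year"] = shifted["birth_year"] + 7
        f1 = fit_trajectory(cohort, one_group_labels(cohort), "y", "g", n_boot=0)
        f2 = fit_trajectory(shifted, one_group_labels(cohort), "y", "g", n_boot=0)
        assert abs(f1.beta_age - f2.beta_age) < 1e-10

    def test_standardized_slope_scale_invariant(self):
        cohort = make_cohort(80, slope=0.4, noise=0.8, seed=4)
        scaled = cohort.copy()
        scaled["y"] = 7.0 * scaled["y"] + 3.0
        f1 = fit_trajectory(cohort, one_group_labels(cohort), "y", "g", n_boot=0)
        f2 = fit_trajectory(scaled, one_group_labels(cohort), "y", "g", n_boot=0)
        assert f1.beta_age == pytest.approx(f2.beta_age, abs=1e-9)

    def test_cluster_resample_contains_whole_subjects_only(self, rng):
        ids = np.repeat([f"s{i}" for i in range(30)], 3)
        idx = _cluster_resample(ids, rng)
        assert len(idx) == 90
        drawn = pd.Series(ids[idx]).value_counts()
        assert (drawn % 3 == 0).all()  # visits always travel together
        groups = _subject_row_groups(ids)
        assert sorted(np.concatenate(groups)) == list(range(90))

    def test_bootstrap_ci_coverage_near_95(self):
        hits = 0
        reps = 200
        for rep in range(reps):
            cohort = make_cohort(60, slope=0.5, noise=1.0, seed=1000 + rep)
            fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g",
                                 standardize_measure=False, n_boot=200, seed=rep)
            hits += int(fit.ci_low <= 0.5 <= fit.ci_high)
        assert 0.92 <= hits / reps <= 0.98

    def test_single_age_and_empty_subgroup_errors(self):
        cohort = make_cohort(20, slope=0.1, noise=0.5, baseline=(30.0, 30.0))
        single = cohort[cohort.visit_id == "v1"]
        with pytest.raises(ValueError, match="single distinct age"):
            fit_trajectory(single, one_group_labels(single), "y", "g", n_boot=0)
        with pytest.raises(ValueError, match="empty"):
            fit_trajectory(cohort, one_group_labels(cohort), "y", "other", n_boot=0)


class TestSlopeAnova:
    def test_type_one_error_calibrated(self):
        """Under a true null (labels independent of trajectories) the
        rejection rate at alpha=0.05 stays near 0.05."""
        rejections = 0
        reps = 150
        for rep in range(reps):
            cohort = make_cohort(40, slope=0.3, noise=1.0, seed=rep)
            rng = np.random.default_rng(rep)
            subs = cohort["subject_id"].unique()
            labels = dict(zip(subs, rng.permutation(np.repeat(list("ab"), 20))))
            res = slope_anova(cohort, labels, "y", n_perm=199, seed=rep)
            rejections += int(res.p_value < 0.05)
        assert 0.01 <= rejections / reps <= 0.10

    def test_power_under_calibrated_slope_spread(self):
        """A divergence of the published size is detected at p<=0.001."""
        hits = 0
        for rep in range(3):
            cfg = two_axis_config(n_subjects=600, baseline_age_range=(24.0, 39.0),
                                  seed=rep)
            cohort = generate_cohort(cfg, "main")
            per = cohort.drop_duplicates("subject_id")
            labels = dict(zip(per.subject_id, per.true_subgroup))
            res = slope_anova(cohort, labels, "div", n_perm=1999, seed=rep)
            hits += int(res.p_value <= 0.001)
        assert hits == 3

    def test_duplicated_subgroup_is_null(self):
        cohort = make_cohort(30, slope=0.5, noise=0.3, seed=9)
        dup = cohort.copy()
        dup["subject_id"] = dup["subject_id"] + "_dup"
        both = pd.concat([cohort, dup], ignore_index=True)
        labels = {s: ("a" if not s.endswith("_dup") else "b")
                  for s in both["subject_id"].unique()}
        res = slope_anova(both, labels, "y", n_perm=199, seed=0)
        assert res.statistic < 1e-12
        assert res.p_value > 0.9

    def test_add_one_rule_minimum_p(self):
        cfg = two_axis_config(n_subjects=400, baseline_age_range=(24.0, 39.0),
                              noise_sd=0.4, subject_sd=0.4)
        cohort = generate_cohort(cfg, "main")
        per = cohort.drop_duplicates("subject_id")
        labels = dict(zip(per.subject_id, per.true_subgroup))
        res = slope_anova(cohort, labels, "div", n_perm=199, seed=0)
        assert res.p_value >= 1 / 200
        assert res.p_value == pytest.approx(1 / 200)


class TestMeanAnova:
    def test_equal_means_rejection_near_alpha(self):
        rejections = 0
        reps = 150
        for rep in range(reps):
            cohort = make_cohort(40, slope=0.0, noise=1.0, seed=rep)
            rng = np.random.default_rng(rep + 999)
            subs = cohort["subject_id"].unique()
            labels = dict(zip(subs, rng.permutation(np.repeat(list("ab"), 20))))
            res = mean_anova(cohort, labels, "y", n_perm=199, seed=rep)
            rejections += int(res.p_value < 0.05)
        assert 0.01 <= rejections / reps <= 0.10

    def test_separated_groups_hit_floor_p(self):
        cohort = make_cohort(1000, slope=0.0, noise=0.5, seed=1)
        subs = cohort["subject_id"].unique()
        labels = {s: ("a" if i < 500 else "b") for i, s in enumerate(subs)}
        shifted = cohort.copy()
        member_b = shifted["subject_id"].map(labels) == "b"
        shifted.loc[member_b, "y"] += 1.0
        res = mean_anova(shifted, labels, "y", n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_single_subgroup_errors(self):
        cohort = make_cohort(20, slope=0.1, noise=0.5)
        with pytest.raises(ValueError, match="2 subgroups"):
            mean_anova(cohort, one_group_labels(cohort), "y", n_perm=199)


class TestCurvesAndAdjustment:
    def test_linear_curve_arithmetic(self):
        """A 2 kg/m^2-per-decade rise from 25 at age 24 reaches 30 at 49."""
        cohort = make_cohort(50, slope=2.0, noise=0.0, intercept=25.0)
        fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g",
                             standardize_measure=False, n_boot=100, seed=0)
        curve = trajectory_curves(fit, ages=np.array([24.0, 49.0]))
        assert curve["yhat"].iloc[0] == pytest.approx(25.0, abs=1e-9)
        assert curve["yhat"].iloc[1] == pytest.approx(30.0, abs=1e-9)

    def test_zero_slope_flat_curve_and_band_contains_point(self):
        cohort = make_cohort(60, slope=0.0, noise=0.6, seed=5)
        fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g",
                             standardize_measure=False, n_boot=300, seed=1)
        curve = trajectory_curves(fit)
        assert np.ptp(curve["yhat"]) == pytest.approx(
            abs(fit.beta_age) * 2.5, abs=1e-12
        )
        assert (curve["lo"] <= curve["yhat"]).all()
        assert (curve["hi"] >= curve["yhat"]).all()

    def test_empty_grid_rejected(self):
        cohort = make_cohort(30, slope=0.1, noise=0.2)
        fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g", n_boot=0)
        with pytest.raises(ValueError, match="empty"):
            trajectory_curves(fit, ages=np.array([]))

    def test_adjusting_a_measure_by_itself_kills_the_slope(self):
        cohort = make_cohort(80, slope=0.5, noise=0.4, seed=6)
        cohort["y2"] = cohort["y"]
        fit = fit_trajectory(cohort, one_group_labels(cohort), "y", "g",
                             adjust_for="y2", n_boot=0)
        assert abs(fit.beta_age) < 1e-9

    def test_shared_latent_divergence_attenuates_under_adjustment(self):
        """BMI-like and WHR-like measures driven by one latent axis:
        adjusting one for the other shrinks the subgroup slope spread."""
        cfg = two_axis_config(
            n_subjects=800,
            baseline_age_range=(24.0, 39.0),
            noise_sd=0.6, subject_sd=0.6,
            extra_measures=(MeasureSpec("bmi_like", loading_axis1=0.9),
                            MeasureSpec("whr_like", loading_axis1=0.9)),
        )
        cohort = generate_cohort(cfg, "main")
        per = cohort.drop_duplicates("subject_id")
        labels = dict(zip(per.subject_id, per.true_subgroup))
        table = adjusted_pair(cohort, labels, "bmi_like", "whr_like",
                              n_boot=0, seed=0)
        spread_un = np.ptp(table["beta_unadjusted"])
        spread_ad = np.ptp(table["beta_adjusted"])
        assert spread_ad < spread_un

    def test_progression_slopes_stay_uniform_under_adjustment(self):
        cfg = two_axis_config(
            n_subjects=800,
            baseline_age_range=(24.0, 39.0),
            noise_sd=0.5, subject_sd=0.5,
            extra_measures=(MeasureSpec("whr_like", loading_axis2=0.9),
                            MeasureSpec("bmi_like", loading_axis1=0.9),),
        )
        cohort = generate_cohort(cfg, "main")
        per = cohort.drop_duplicates("subject_id")
        labels = dict(zip(per.subject_id, per.true_subgroup))
        table = adjusted_pair(cohort, labels, "whr_like", "bmi_like",
                              n_boot=0, seed=0)
        assert np.ptp(table["beta_adjusted"]) < 0.15
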