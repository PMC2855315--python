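"""Cross-validation, classification bands, permutation null, power curve,
and human-agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hedonose as hn


def permutation_p_oracle(x, y, n_shuffles=10_000, seed=0):
    """Two-sided permutation p for a Pearson correlation, by brute force."""
    rng = np.random.default_rng(seed)
    observed = abs(stats.pearsonr(x, y)[0])
    count = 0
    for _ in range(n_shuffles):
        if abs(stats.pearsonr(x, rng.permutation(y))[0]) >= observed:
            count += 1
    return (count + 1) / (n_shuffles + 1)


class TestPearsonP:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_t_transform_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = 0.6 * x + rng.normal(size=8)
        _, p_t = stats.pearsonr(x, y)
        p_perm = permutation_p_oracle(x, y, seed=seed)
        # Monte-Carlo error of p_perm is ~sqrt(p(1-p)/1e4) < 0.005; the
        # t-approximation itself is good to a few hundredths at n=8
        assert p_t == pytest.approx(p_perm, abs=0.03)


class TestLeaveGroupOut:
    def test_group_below_three_rejected(self, prepared, targets):
        feats, _ = prepared
        with pytest.raises(ValueError, match="group_size"):
            hn.leave_group_out(feats, targets, group_size=2)

    def test_noiseless_pipeline_always_significant(self, noiseless_setup):
        lib, mset = noiseless_setup
        feats, _ = hn.prepare_features(mset)
        cv = hn.leave_group_out(
            feats, lib.truth_series(), group_size=15, n_repeats=5, seed=0
        )
        assert cv.fraction_significant == 1.0
        assert cv.median_r > 0.8

    def test_scrambled_labels_calibrate_to_nominal_alpha(self, prepared, targets):
        # with targets randomly reassigned to odorants the fraction of
        # repeats reaching p < 0.05 should be near the 5% nominal level
        feats, _ = prepared
        rng = np.random.default_rng(123)
        odorants = list(dict.fromkeys(feats.odorant_ids))
        values = np.array([targets[o] for o in odorants])
        scrambled = pd.Series(values[rng.permutation(len(values))], index=odorants)
        cv = hn.leave_group_out(feats, scrambled, group_size=25, n_repeats=40, seed=7)
        # binomial(40, 0.05): P(X >= 8) < 1e-3
        assert cv.fraction_significant <= 0.175
        assert abs(cv.mean_r) < 0.25


class TestClassificationAccuracy:
    def test_toy_enumeration(self):
        preds = pd.Series({"a": 2.0, "b": -1.0, "c": 1.0})
        vas = pd.Series({"a": 25.0, "b": 5.0, "c": 4.0})
        out = hn.classification_accuracy(preds, vas)
        assert out["accuracy"] == pytest.approx(2 / 3)
        assert out["n_scored"] == 3

    def test_perfect_predictions_with_wide_band(self):
        vas = pd.Series({"a": 25.0, "b": 5.0, "c": 15.5, "d": 28.0})
        preds = vas - 15.0
        out = hn.classification_accuracy(preds, vas, hn.ExclusionBand(10, 20))
        assert out["accuracy"] == 1.0
        assert out["n_excluded"] == 1

    def test_all_odorants_excluded_rejected(self):
        vas = pd.Series({"a": 15.0, "b": 14.0})
        with pytest.raises(ValueError, match="exclusion band"):
            hn.classification_accuracy(vas - 15, vas, hn.ExclusionBand(10, 20))

    def test_per_measurement_secondary_accuracy(self):
        preds = pd.Series({"a": 2.0, "b": -1.0})
        vas = pd.Series({"a": 25.0, "b": 5.0})
        samples = pd.Series({"a:1": 2.0, "a:2": -0.5, "b:1": -1.0})
        out = hn.classification_accuracy(
            preds, vas, sample_predictions=samples,
            sample_odorants={"a:1": "a", "a:2": "a", "b:1": "b"},
        )
        assert out["per_measurement_accuracy"] == pytest.approx(2 / 3)


class TestExclusionSweep:
    def test_widening_bands_exclude_monotonically(self, prepared, targets):
        feats, _ = prepared
        res = hn.PleasantnessModel(feats, targets).fit(seed=0)
        _, preds = res.predict(feats)
        sweep = hn.exclusion_sweep(preds, targets.median_vas)
        excluded = [row["n_excluded"] for row in sweep]
        assert excluded == sorted(excluded)
        assert sweep[0]["band"] == "none"
        assert sweep[-1]["band"] == "10-20"

    def test_sweep_consistent_with_single_band_call(self, prepared, targets):
        feats, _ = prepared
        res = hn.PleasantnessModel(feats, targets).fit(seed=0)
        _, preds = res.predict(feats)
        sweep = hn.exclusion_sweep(preds, targets.median_vas)
        single = hn.classification_accuracy(
            preds, targets.median_vas, hn.ExclusionBand(10, 20)
        )
        assert sweep[-1]["accuracy"] == single["accuracy"]

    def test_accuracy_tends_up_as_mid_scale_removed(self, prepared, targets):
        feats, _ = prepared
        res = hn.PleasantnessModel(feats, targets).fit(seed=0)
        _, preds = res.predict(feats)
        sweep = hn.exclusion_sweep(preds, targets.median_vas)
        assert sweep[-1]["accuracy"] >= sweep[0]["accuracy"] - 0.02


class TestPermutationControl:
    def test_null_mean_near_zero(self, prepared, targets):
        feats, _ = prepared
        out = hn.permutation_control(feats, targets, n_perm=30, seed=3)
        assert abs(out.mean_r) <= 0.08
        assert out.mean_p > 0.1

    def test_small_and_large_runs_agree(self, prepared, targets):
        feats, _ = prepared
        small = hn.permutation_control(feats, targets, n_perm=10, seed=5)
        large = hn.permutation_control(feats, targets, n_perm=60, seed=6)
        se = np.std(large.r_values) / np.sqrt(10)
        assert abs(small.mean_r - large.mean_r) <= 3 * se + 0.02

    def test_too_few_permutations_rejected(self, prepared, targets):
        feats, _ = prepared
        with pytest.raises(ValueError, match="n_perm"):
            hn.permutation_control(feats, targets, n_perm=5)


class TestPowerCurve:
    def test_learning_curve_rises_and_small_sizes_degrade(self, prepared, targets):
        feats, _ = prepared
        curve = hn.power_curve(
            feats, targets, training_sizes=[5, 20, 45], n_repeats=8, seed=4,
            test_size=15,
        )
        r = curve.set_index("training_size")["mean_r"]
        assert r[45] >= r[5]
        assert r[45] >= r[20] - 0.05  # non-decreasing within sampling error
        fp = curve.set_index("training_size")["fraction_p_above_0.05"]
        assert fp[5] >= fp[45]

    def test_oversized_training_request_rejected(self, prepared, targets):
        feats, _ = prepared
        with pytest.raises(ValueError, match="training size"):
            hn.power_curve(feats, targets, training_sizes=[70], test_size=15)


class TestAgreement:
    def test_worked_percent_examples(self):
        assert hn.machine_human_percent(0.64, 0.72) == 88
        assert hn.machine_human_percent(0.52, 0.60) == 86
        # the third printed pair is consistent only with nearest rounding;
        # truncation gives 81
        assert hn.machine_human_percent(0.45, 0.55) == 81
        assert hn.machine_human_percent(0.45, 0.55, mode="nearest") == 82

    def test_machine_equal_to_median_gives_100_percent(self):
        lib = hn.generate_library(22, seed=8)
        ratings = hn.generate_ratings(lib, hn.RaterModel(n_subjects=10), seed=8)
        median = ratings.to_frame().groupby("odorant")["vas"].median()
        report = hn.agreement_stats(ratings, median)
        assert report.machine_human_r == pytest.approx(1.0)
        assert report.percent_of_human >= 100

    def test_all_statistics_decrease_with_subject_noise(self):
        lib = hn.generate_library(22, seed=9)
        machine = lib.truth_series() - 15.0
        stats_by_noise = {}
        for sigma in (3.0, 9.0):
            vals = []
            for seed in (0, 1):
                ratings = hn.generate_ratings(
                    lib, hn.RaterModel(n_subjects=12, sigma_subj=sigma), seed=seed
                )
                rep = hn.agreement_stats(ratings, machine)
                vals.append(
                    (rep.pairwise_human_r, rep.human_to_median_r, rep.test_retest_r,
                     rep.machine_human_r)
                )
            stats_by_noise[sigma] = np.mean(vals, axis=0)
        assert (stats_by_noise[9.0] < stats_by_noise[3.0]).all()

    def test_single_session_subject_excluded_from_retest_only(self):
        lib = hn.generate_library(8, seed=10)
        ratings = hn.generate_ratings(lib, hn.RaterModel(n_subjects=3), seed=10)
        frame = ratings.to_frame()
        frame = frame[~((frame["subject"] == frame["subject"].iloc[0])
                        & (frame["session"] == 2))]
        report = hn.agreement_stats(
            hn.RatingTable(frame), lib.truth_series() - 15.0
        )
        assert report.n_subjects == 3  # still counted for pairwise/median stats
        assert np.isfinite(report.test_retest_r)
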