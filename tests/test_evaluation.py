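"""Validation metrics, cross-validation, greedy selection, holdout,
leave-one-subject-out and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from epibeat.evaluation import (accuracy_and_loss, anova_one_way,
                                confusion_matrix, greedy_feature_search,
                                holdout_validate, kfold_validate,
                                leave_one_subject_out,
                                stratified_fold_indices,
                                stratified_holdout_split)


def feature_frame(rng, n=240, n_classes=4, informative="F03", noise=0.15,
                  codes=None, subject_effect=0.0, n_subjects=3):
    """Synthetic table: one feature tracks the class, the rest are noise."""
    codes = codes or [f"F{i:02d}" for i in range(8)]
    y = rng.integers(0, n_classes, n)
    data = {c: rng.normal(0, 1, n) for c in codes}
    subjects = np.array([f"s{i % n_subjects}" for i in range(n)])
    gains = {f"s{i}": 1.0 + subject_effect * (i - 1) for i in range(
        n_subjects)}
    g = np.array([gains[s] for s in subjects])
    data[informative] = g * (y + rng.normal(0, noise, n))
    df = pd.DataFrame(data)
    df["label"] = y
    df["subject"] = subjects
    return df


class TestMetrics:
    def test_all_correct(self):
        assert accuracy_and_loss([1, 2, 3], [1, 2, 3]) == (1.0, 0.0)

    def test_off_by_one_everywhere(self):
        acc, loss = accuracy_and_loss([0, 1, 2], [1, 2, 3])
        assert (acc, loss) == (0.0, 1.0)

    def test_hand_computed_example(self):
        acc, loss = accuracy_and_loss([0, 1, 2], [0, 1, 0])
        assert acc == pytest.approx(2 / 3)
        assert loss == pytest.approx(4 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy_and_loss([0, 1], [0])

    def test_loss_zero_iff_accuracy_one(self, rng):
        for _ in range(20):
            y = rng.integers(0, 4, 30)
            yh = rng.integers(0, 4, 30)
            acc, loss = accuracy_and_loss(y, yh)
            assert (loss == 0.0) == (acc == 1.0)


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.all(cm == np.diag([1, 2, 1]))

    def test_hand_count(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_total_and_trace_identities(self, rng):
        y = rng.integers(0, 3, 50)
        yh = rng.integers(0, 3, 50)
        cm = confusion_matrix(y, yh, 3)
        assert cm.sum() == 50
        acc, _ = accuracy_and_loss(y, yh)
        assert np.trace(cm) / cm.sum() == pytest.approx(acc)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1], 3)


class TestFolds:
    def test_stratification_balances_classes(self, rng):
        y = np.repeat([0, 1, 2], 40)
        folds = stratified_fold_indices(y, 4, rng)
        for c in range(3):
            counts = np.bincount(folds[y == c], minlength=4)
            assert counts.max() - counts.min() <= 1

    def test_separable_task_perfect_cv(self, rng):
        df = feature_frame(rng, noise=0.01)
        rep = kfold_validate(df, ("F03",), "label", 4, k=5, seed=0,
                             n_trees=10)
        assert rep.accuracy > 0.97
        assert rep.loss < 0.05

    def test_permuted_labels_fall_to_chance(self, rng):
        df = feature_frame(rng, n=400, noise=0.01)
        df["label"] = rng.permutation(df["label"].to_numpy())
        rep = kfold_validate(df, ("F03",), "label", 4, k=5, seed=0,
                             n_trees=10)
        assert rep.accuracy == pytest.approx(0.25, abs=0.08)

    def test_seed_determinism(self, rng):
        df = feature_frame(rng)
        r1 = kfold_validate(df, ("F03", "F01"), "label", 4, k=5, seed=9)
        r2 = kfold_validate(df, ("F03", "F01"), "label", 4, k=5, seed=9)
        assert r1.accuracy == r2.accuracy
        assert r1.fold_accuracies == r2.fold_accuracies
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_confusion_consistent_with_accuracy(self, rng):
        df = feature_frame(rng)
        rep = kfold_validate(df, ("F03",), "label", 4, k=5, seed=1,
                             n_trees=10)
        pooled = np.trace(rep.confusion) / rep.confusion.sum()
        # fold-mean accuracy equals pooled accuracy for equal-size folds
        assert rep.accuracy == pytest.approx(pooled, abs=0.02)


class TestGreedySearch:
    def test_planted_feature_recovered_first(self, rng):
        df = feature_frame(rng, informative="F05")
        subset, trace = greedy_feature_search(
            df, [c for c in df.columns if c.startswith("F")], "label", 4,
            k=4, seed=0, n_trees=8)
        assert trace.steps[0]["subset"] == ["F05"]
        assert "F05" in subset

    def test_complementary_pair_selected(self, rng):
        """Two XOR-style features are each useless alone but jointly
        separable; stage 2 must pick up the partner."""
        n = 300
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        y = ((a > 0) ^ (b > 0)).astype(int)
        df = pd.DataFrame({"A": a, "B": b,
                           "N1": rng.normal(0, 1, n),
                           "N2": rng.normal(0, 1, n),
                           "label": y})
        subset, _ = greedy_feature_search(
            df, ("A", "B", "N1", "N2"), "label", 2, k=4, seed=0,
            n_trees=10, max_splits=8)
        assert {"A", "B"} <= set(subset)

    def test_pure_noise_stops_near_chance(self, rng):
        df = feature_frame(rng, noise=1.0)
        df["F03"] = rng.normal(0, 1, len(df))  # kill the signal
        subset, trace = greedy_feature_search(
            df, [c for c in df.columns if c.startswith("F")], "label", 4,
            k=4, seed=0, n_trees=8)
        final = trace.steps[-1]
        assert final["cv_accuracy"] < 0.45

    def test_result_never_worse_than_best_single(self, rng):
        df = feature_frame(rng, noise=0.3)
        codes = [c for c in df.columns if c.startswith("F")]
        subset, trace = greedy_feature_search(df, codes, "label", 4,
                                              k=4, seed=2, n_trees=8)
        singles = [s["cv_accuracy"] for s in trace.steps
                   if len(s["subset"]) == 1 and s["action"] == "add"]
        assert trace.steps[-1]["cv_accuracy"] >= max(singles) - 1e-12

    def test_subset_capped_at_three(self, rng):
        df = feature_frame(rng, noise=0.2)
        codes = [c for c in df.columns if c.startswith("F")]
        subset, _ = greedy_feature_search(df, codes, "label", 4, k=4,
                                          seed=3, n_trees=8)
        assert 1 <= len(subset) <= 3

    def test_loss_metric_optimization(self, rng):
        df = feature_frame(rng)
        subset, trace = greedy_feature_search(
            df, [c for c in df.columns if c.startswith("F")], "label", 4,
            metric="loss", k=4, seed=0, n_trees=8)
        assert "F03" in subset


class TestHoldout:
    def test_five_percent_of_hundred(self, rng):
        df = pd.DataFrame({"label": np.zeros(100, int),
                           "x": rng.normal(0, 1, 100)})
        train, hold = stratified_holdout_split(df, "label", 0.05, 10, 0)
        assert len(hold) == 5

    def test_scarce_class_reduction(self, rng):
        df = pd.DataFrame({"label": np.zeros(8, int),
                           "x": rng.normal(0, 1, 8)})
        train, hold = stratified_holdout_split(df, "label", 0.05, 10, 0)
        assert len(hold) == 0 and len(train) == 8

    def test_partition(self, rng):
        df = feature_frame(rng)
        train, hold = stratified_holdout_split(df, "label", 0.10, 5, 1)
        assert len(train) + len(hold) == len(df)
        assert set(train.index).isdisjoint(hold.index)

    def test_holdout_validate_reports(self, rng):
        df = feature_frame(rng, noise=0.05)
        train, hold = stratified_holdout_split(df, "label", 0.2, 5, 2)
        rep, ens = holdout_validate(train, hold, ("F03",), "label", 4,
                                    seed=0, n_trees=10)
        assert rep.mode == "holdout"
        assert rep.accuracy > 0.8
        assert rep.confusion.sum() == len(hold)


class TestLoso:
    def test_one_report_per_subject(self, rng):
        df = feature_frame(rng, n=360, n_subjects=5, noise=0.2)
        reports = leave_one_subject_out(
            df, [c for c in df.columns if c.startswith("F")], "label", 4,
            k=3, seed=0, n_trees=8)
        assert len(reports) == 5
        assert {r.subject for r in reports} == set(df["subject"].unique())

    def test_homogeneous_subjects_match_pooled_cv(self, rng):
        df = feature_frame(rng, n=360, noise=0.05, subject_effect=0.0)
        reports = leave_one_subject_out(
            df, ("F03", "F01"), "label", 4, k=3, seed=1, n_trees=10)
        pooled = kfold_validate(df, ("F03",), "label", 4, k=5, seed=1,
                                n_trees=10)
        loso_mean = np.mean([r.accuracy for r in reports])
        assert loso_mean == pytest.approx(pooled.accuracy, abs=0.1)

    def test_subject_effects_degrade_generalization(self, rng):
        df = feature_frame(rng, n=360, noise=0.05, subject_effect=0.35)
        reports = leave_one_subject_out(
            df, ("F03",), "label", 4, k=3, seed=2, n_trees=10)
        pooled = kfold_validate(df, ("F03",), "label", 4, k=5, seed=2,
                                n_trees=10)
        loso_mean = np.mean([r.accuracy for r in reports])
        assert loso_mean < pooled.accuracy

    def test_single_subject_rejected(self, rng):
        df = feature_frame(rng, n_subjects=1)
        with pytest.raises(ValueError):
            leave_one_subject_out(df, ("F03",), "label", 4)


class TestAnova:
    def test_equal_groups_zero_f(self):
        f, p = anova_one_way([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        f, p = anova_one_way([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        from scipy import stats
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2), rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_one_way([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            anova_one_way([[1, 2]])
        with pytest.raises(ValueError):
            anova_one_way([[1], [2, 3]])

    def test_type_one_error_calibration(self, rng):
        """Under the null, p-values are roughly uniform."""
        ps = []
        for _ in range(200):
            groups = [rng.normal(0, 1, 6) for _ in range(3)]
            ps.append(anova_one_way(groups)[1])
        ps = np.array(ps)
        assert 0.01 < np.mean(ps < 0.05) < 0.12
        assert abs(np.mean(ps) - 0.5) < 0.1


class TestBinWidthMonotonicity:
    def test_coarser_bins_never_reduce_accuracy(self, rng):
        """Re-binning the same continuous estimates at coarser widths
        cannot lower exact-match accuracy."""
        from epibeat.reference import BinningScheme, bin_value

        truth = rng.uniform(60, 130, 400)
        estimate = truth + rng.normal(0, 4.0, 400)
        accs = []
        for width in (5.0, 10.0, 20.0):
            scheme = BinningScheme(60.0, 130.0, width)
            yt = [bin_value(v, scheme) for v in truth]
            ye = [bin_value(v, scheme) for v in estimate]
            accs.append(accuracy_and_loss(yt, ye)[0])
        assert accs[0] <= accs[1] <= accs[2]
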