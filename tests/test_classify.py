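"""LOSO classification: balanced accuracy, tuning, leakage, summaries."""

import numpy as np
import pandas as pd
import pytest

import tscs_tune as tt
from tscs_tune import classify as clf


def balanced_accuracy_oracle(y_true, y_pred) -> float:
    """Direct per-class recall averaging, written independently."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = []
    for c in sorted(set(y_true.tolist())):
        mask = y_true == c
        recalls.append(np.sum(y_pred[mask] == c) / np.sum(mask))
    return sum(recalls) / len(recalls)


def separable_table(n_subjects=6, n_per_subject=30, n_classes=3, seed=0,
                    shift=50.0) -> pd.DataFrame:
    """Feature table whose MMG columns carry a large class-mean shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for _ in range(n_per_subject):
            label = int(rng.integers(n_classes))
            feats = {name: float(rng.normal(label * shift, 1.0))
                     for name in tt.features.MMG_FEATURES}
            feats.update({name: float(rng.normal())
                          for name in tt.features.META_FEATURES})
            feats.update({name: float(rng.normal())
                          for name in tt.features.STIM_FEATURES})
            rows.append({"subject_id": f"S{s}", "group": "healthy",
                         "position": 0.0, "day": 1, "current_ma": 10.0,
                         "muscle": "Q_left", "label_2": int(label > 0),
                         "label_3": label, **feats})
    return pd.DataFrame(rows)


class TestBalancedAccuracy:
    @pytest.mark.parametrize("y_true,y_pred,expected", [
        ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),
        ([0, 0, 1, 1], [0, 0, 0, 0], 0.5),
        ([0, 0, 1, 1, 2], [0, 1, 1, 1, 2], (0.5 + 1 + 1) / 3),
    ])
    def test_known_values(self, y_true, y_pred, expected):
        assert tt.balanced_accuracy(y_true, y_pred) == pytest.approx(expected)

    def test_matches_oracle_on_random_vectors(self, rng):
        """1000 random label vectors agree with brute-force per-class
        recall averaging to 1e-12."""
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, 3, n)
            y_pred = rng.integers(0, 3, n)
            a = tt.balanced_accuracy(y_true, y_pred)
            b = balanced_accuracy_oracle(y_true, y_pred)
            assert abs(a - b) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tt.balanced_accuracy([], [])


class TestTuning:
    def test_single_iteration_returns_single_sample(self):
        table = separable_table(n_subjects=3, n_per_subject=10)
        X, y, groups = tt.select_feature_set(table, "SET-OBSERVE")
        params = tt.tune_hyperparameters(X, np.asarray(y), np.asarray(groups),
                                         "RF", n_iter=1, seed=5)
        rng = np.random.default_rng(5)
        assert params == clf.sample_params("RF", rng)

    def test_same_seed_same_choice(self):
        table = separable_table(n_subjects=3, n_per_subject=10)
        X, y, groups = tt.select_feature_set(table, "SET-OBSERVE")
        a = tt.tune_hyperparameters(X, np.asarray(y), np.asarray(groups),
                                    "SVM", n_iter=4, seed=9)
        b = tt.tune_hyperparameters(X, np.asarray(y), np.asarray(groups),
                                    "SVM", n_iter=4, seed=9)
        assert a == b

    def test_chosen_beats_default_on_separable_data(self):
        """The argmax of the sampled settings scores at least as well as a
        fixed default setting under the same inner LOSO."""
        table = separable_table(n_subjects=4, n_per_subject=15)
        X, y, groups = (np.asarray(v) for v in
                        tt.select_feature_set(table, "SET-OBSERVE"))
        Xdf = table[tt.features.FEATURE_SETS["SET-OBSERVE"]]

        def inner_score(params):
            scores = []
            for s in np.unique(groups):
                te = groups == s
                scores.append(clf._fit_score("RF", params, 3,
                                             Xdf[~te], y[~te],
                                             Xdf[te], y[te], 0))
            return np.mean(scores)

        best = tt.tune_hyperparameters(Xdf, y, groups, "RF", n_iter=3, seed=2)
        default = {"min_samples_split": 2, "min_samples_leaf": 1,
                   "max_depth": None, "max_samples": 1.0}
        assert inner_score(best) >= inner_score(default) - 1e-9

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            tt.tune_hyperparameters(pd.DataFrame([[0.0]]), np.array([0]),
                                    np.array(["a"]), "RF", n_iter=0, seed=0)


class TestLoso:
    def test_fold_count_and_no_test_subject_in_training(self):
        table = separable_table(n_subjects=5, n_per_subject=12)
        cfg = tt.ExperimentConfig(n_classes=3, model_family="RF",
                                  search_iterations=1, seed=0)
        folds, _ = clf.run_experiment(table, cfg)
        assert len(folds) == 5
        for f in folds:
            assert f.test_subject not in f.train_subjects
            # predictions cover exactly the test subject's rows
            rows = table.loc[f.predictions.index]
            assert (rows.subject_id == f.test_subject).all()

    def test_separable_data_perfect_rf_folds(self):
        """A large class-dependent mean shift makes every fold perfect."""
        table = separable_table(n_subjects=5, n_per_subject=20, shift=100.0)
        cfg = tt.ExperimentConfig(n_classes=3, model_family="RF",
                                  search_iterations=1, seed=1)
        folds, summary = clf.run_experiment(table, cfg)
        assert all(f.balanced_accuracy == 1.0 for f in folds)
        assert summary.mean_balanced_accuracy == 1.0
        assert summary.std_balanced_accuracy == 0.0

    def test_no_leakage_from_test_labels(self):
        """Corrupting the test subject's labels leaves its predictions
        unchanged (they never reach the trained model)."""
        table = separable_table(n_subjects=4, n_per_subject=15)
        X, y, groups = tt.select_feature_set(table, "SET-OBSERVE")
        cfg = tt.ExperimentConfig(model_family="RF", search_iterations=1,
                                  seed=3)
        params = {"min_samples_split": 2, "min_samples_leaf": 1,
                  "max_depth": None, "max_samples": 0.9}
        folds_a = tt.loso_cross_validate(X, y, groups, cfg,
                                         fixed_params=params)
        y_corrupt = y.copy()
        test_subject = folds_a[0].test_subject
        mask = np.asarray(groups) == test_subject
        y_corrupt[mask] = np.random.default_rng(0).integers(0, 3,
                                                            mask.sum())
        folds_b = tt.loso_cross_validate(X, pd.Series(y_corrupt), groups,
                                         cfg, fixed_params=params)
        pd.testing.assert_series_equal(folds_a[0].predictions,
                                       folds_b[0].predictions)

    def test_permuted_labels_score_at_chance(self, rng):
        """Labels shuffled independently of the features give 2-class
        balanced accuracy at chance (0.5) within 3 sigma."""
        table = separable_table(n_subjects=4, n_per_subject=20, n_classes=2,
                                shift=100.0)
        params = {"min_samples_split": 2, "min_samples_leaf": 1,
                  "max_depth": 5, "max_samples": 0.9}
        means = []
        for perm in range(20):
            t = table.copy()
            y = rng.permutation(t["label_2"].to_numpy())
            t["label_2"] = y
            t["label_3"] = y
            cfg = tt.ExperimentConfig(n_classes=2, model_family="RF",
                                      search_iterations=1, seed=perm)
            X, _, groups = tt.select_feature_set(t, "SET-OBSERVE")
            folds = tt.loso_cross_validate(X, t["label_2"], groups, cfg,
                                           fixed_params=params)
            means.append(np.mean([f.balanced_accuracy for f in folds]))
        grand = np.mean(means)
        sem = np.std(means) / np.sqrt(len(means))
        assert abs(grand - 0.5) <= 3 * max(sem, 0.01)

    def test_single_subject_rejected(self):
        table = separable_table(n_subjects=1)
        cfg = tt.ExperimentConfig(search_iterations=1)
        with pytest.raises(ValueError):
            clf.run_experiment(table, cfg)


class TestSummaries:
    def test_single_fold_mean_and_zero_std(self):
        f = clf.FoldResult("S0", 0.8, pd.Series([0, 1]),
                           np.array([[1, 0], [0, 1]]))
        s = tt.summarize_experiments([f], (0, 1))
        assert s.mean_balanced_accuracy == 0.8
        assert s.std_balanced_accuracy == 0.0

    def test_confusion_conservation_and_row_ratio(self):
        table = separable_table(n_subjects=4, n_per_subject=10)
        cfg = tt.ExperimentConfig(model_family="RF", search_iterations=1,
                                  seed=0)
        folds, summary = clf.run_experiment(table, cfg)
        n_events = sum(len(f.predictions) for f in folds)
        assert summary.confusion_sum.sum() == n_events == len(table)
        rowsums = summary.confusion_rowratio.sum(axis=1)
        present = summary.confusion_sum.sum(axis=1) > 0
        np.testing.assert_allclose(rowsums[present], 1.0, atol=1e-12)

    def test_grid_enumerates_36_combinations(self):
        grid = tt.experiment_grid()
        assert len(grid) == 36
        ids = {g.config_id for g in grid}
        assert len(ids) == 36


class TestObserveBeatsPredict:
    def test_sensor_features_outperform_sensorless(self, low_noise_cohort):
        """When the acceleration carries the class signal and meta/stim do
        not fully determine it, SET-OBSERVE is at least as accurate as
        SET-PREDICT (within a small slack)."""
        table = low_noise_cohort["table"]
        accs = {}
        for fs in ("SET-OBSERVE", "SET-PREDICT"):
            cfg = tt.ExperimentConfig(feature_set=fs, n_classes=2,
                                      model_family="RF",
                                      search_iterations=2, seed=4)
            _, summary = clf.run_experiment(table, cfg)
            accs[fs] = summary.mean_balanced_accuracy
        assert accs["SET-OBSERVE"] >= accs["SET-PREDICT"] - 0.02
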