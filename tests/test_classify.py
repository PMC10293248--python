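import numpy as np
import pandas as pd
import pytest

from spiraldx.classify import (ModelConfig, TaskClassifier, error_analysis,
                               majority_baseline, make_task_dataset, run_cv,
                               shap_importance)
from spiraldx.errors import DomainError, ValidationError
from spiraldx.features import FEATURE_NAMES
from spiraldx.stats import TASKS


def synthetic_table(n_cg=27, n_pd=24, n_dd=26, seed=0, signal=True):
    """Feature table with a controllable class signal in QYes and F2."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("CG", n_cg), ("PD", n_pd), ("DD", n_dd)):
        for i in range(n):
            diseased = group != "CG"
            row = {"participant_id": f"{group}{i}", "group": group,
                   "age": float(rng.normal(60, 8)),
                   "gender": "female" if rng.random() < 0.5 else "male",
                   "hoehn_yahr": 2.0 if group == "PD" else np.nan}
            for feat in FEATURE_NAMES:
                row[feat] = float(rng.normal(0, 1))
            if signal:
                row["QYes"] = float(rng.normal(12 if diseased else 3, 2))
                row["F2_MaxDistance"] = float(
                    rng.normal(0.25 if group == "PD" else 0.1, 0.03))
            rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


class TestTaskDataset:
    @pytest.mark.parametrize("task, expected_rows", [
        ("Task1", 51), ("Task2", 77), ("Task3", 50),
    ])
    def test_row_counts_for_published_cohort_sizes(self, task, expected_rows):
        X, y, _ = make_task_dataset(synthetic_table(), TASKS[task])
        assert len(X) == expected_rows

    def test_questionnaire_only_has_one_predictor(self):
        X, _, _ = make_task_dataset(synthetic_table(), TASKS["Task1"],
                                    "questionnaire_only")
        assert list(X.columns) == ["QYes"]

    def test_tablet_only_excludes_questionnaire(self):
        X, _, _ = make_task_dataset(synthetic_table(), TASKS["Task1"], "tablet_only")
        assert "QYes" not in X.columns and X.shape[1] == 13

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(DomainError):
            make_task_dataset(synthetic_table(), TASKS["Task1"], "everything")


class TestMajorityBaseline:
    @pytest.mark.parametrize("task, expected", [
        ("Task1", 0.53), ("Task2", 0.65), ("Task3", 0.52),
    ])
    def test_published_cohort_sizes(self, task, expected):
        _, y, _ = make_task_dataset(synthetic_table(), TASKS[task])
        assert round(majority_baseline(y), 2) == expected

    def test_single_class_warns(self):
        with pytest.warns(UserWarning):
            assert majority_baseline(np.zeros(20)) == 1.0


class TestRunCV:
    def test_perfectly_separable_feature_gives_full_accuracy(self):
        df = synthetic_table(seed=3)
        df["QYes"] = np.where(df["group"] == "PD", 25.0, 2.0)
        X, y, _ = make_task_dataset(df, TASKS["Task1"], "questionnaire_only")
        cv = run_cv(X, y, ModelConfig(seed=0))
        assert cv.mean_metrics["accuracy"] == 1.0

    def test_shuffled_labels_score_near_baseline(self):
        df = synthetic_table(seed=1, signal=False)
        X, y, _ = make_task_dataset(df, TASKS["Task1"])
        cv = run_cv(X, y, ModelConfig(seed=1))
        assert abs(cv.mean_metrics["accuracy"] - majority_baseline(y)) <= 0.15

    def test_every_participant_predicted_once(self):
        X, y, _ = make_task_dataset(synthetic_table(), TASKS["Task1"])
        cv = run_cv(X, y, ModelConfig(seed=2))
        assert not cv.oof_prediction.isna().any()
        assert cv.fold_metrics["n_test"].sum() == len(y)

    def test_stratification_within_one_sample(self):
        X, y, _ = make_task_dataset(synthetic_table(), TASKS["Task2"])
        cv = run_cv(X, y, ModelConfig(seed=0))
        global_rate = y.mean()
        for fold in range(5):
            mask = cv.fold_assignment == fold
            n_pos = int(y[mask].sum())
            assert abs(n_pos - global_rate * mask.sum()) <= 1.0

    def test_seeded_determinism(self):
        X, y, _ = make_task_dataset(synthetic_table(), TASKS["Task1"])
        cv1 = run_cv(X, y, ModelConfig(seed=11))
        cv2 = run_cv(X, y, ModelConfig(seed=11))
        pd.testing.assert_frame_equal(cv1.fold_metrics, cv2.fold_metrics)
        pd.testing.assert_series_equal(cv1.oof_probability, cv2.oof_probability)

    def test_fold_refit_differs_from_leaky_preprocessing(self):
        """Fitting scaler/PCA on the full data before the split must change
        the test predictions — i.e. fold-wise refitting really happens.

        Signal-free features: with a cleanly separable feature both variants
        find the same pure-class partition and the check would be vacuous."""
        X, y, _ = make_task_dataset(synthetic_table(seed=5, signal=False),
                                    TASKS["Task1"])
        clean = run_cv(X, y, ModelConfig(seed=4))
        leaky = run_cv(X, y, ModelConfig(seed=4), _leak_preprocessing=True)
        assert not np.allclose(clean.oof_probability, leaky.oof_probability)

    def test_small_class_rejected_with_hint(self):
        df = synthetic_table(n_cg=4, n_pd=20, n_dd=5)
        X, y, _ = make_task_dataset(df, TASKS["Task1"])
        with pytest.raises(ValidationError, match="folds"):
            run_cv(X, y, ModelConfig(n_folds=5))


class TestShapImportance:
    @pytest.fixture(scope="class")
    def fitted(self):
        df = synthetic_table(seed=9)
        results = TaskClassifier(df, "Task1", "integrated", ModelConfig(seed=9)).fit()
        return results, results.shap_importance()

    def test_additivity_to_model_output(self, fitted):
        _, report = fitted
        for phi, base, margins, _ in report.per_sample:
            np.testing.assert_allclose(phi.sum(axis=1) + base, margins,
                                       atol=1e-6)

    def test_signal_feature_ranks_first(self, fitted):
        _, report = fitted
        assert report.mean_abs_ranking.index[0] == "QYes"

    def test_pure_noise_feature_ranks_behind_signal(self, fitted):
        _, report = fitted
        ranking = report.mean_abs_ranking
        # F10 carries no class signal in this table
        assert ranking["F10_MedianForce"] < ranking["QYes"]
        assert ranking["F10_MedianForce"] <= ranking.min() + 1e-12

    def test_one_row_per_feature_per_fold(self, fitted):
        _, report = fitted
        assert report.per_fold_mean.shape == (5, 14)
        assert list(report.per_fold_mean.columns) == list(FEATURE_NAMES)


class TestErrorAnalysis:
    def test_perfect_classifier_has_empty_subgroups(self):
        df = synthetic_table(seed=3)
        df["QYes"] = np.where(df["group"] == "PD", 25.0, 2.0)
        X, y, meta = make_task_dataset(df, TASKS["Task1"], "questionnaire_only")
        cv = run_cv(X, y, ModelConfig(seed=0))
        table = error_analysis(cv, meta, TASKS["Task1"])
        assert (table["count"] == 0).all()
        assert table["mean_age"].isna().all()

    def test_known_false_positives_statistics(self):
        df = synthetic_table(seed=3)
        df["QYes"] = np.where(df["group"] == "PD", 25.0, 2.0)
        X, y, meta = make_task_dataset(df, TASKS["Task1"], "questionnaire_only")
        cv = run_cv(X, y, ModelConfig(seed=0))
        # force two known control participants to be predicted positive
        fp_ids = meta.index[meta["group"] == "CG"][:2]
        meta = meta.copy()
        meta.loc[fp_ids[0], "age"] = 50.0
        meta.loc[fp_ids[1], "age"] = 60.0
        cv.oof_prediction.loc[fp_ids] = 1
        table = error_analysis(cv, meta, TASKS["Task1"]).set_index("error_class")
        assert table.loc["FP", "count"] == 2
        assert table.loc["FP", "mean_age"] == pytest.approx(55.0)

    def test_task2_false_negatives_split_by_subgroup(self):
        df = synthetic_table(seed=6)
        X, y, meta = make_task_dataset(df, TASKS["Task2"])
        cv = run_cv(X, y, ModelConfig(seed=6))
        table = error_analysis(cv, meta, TASKS["Task2"])
        assert set(table["error_class"]) == {"FP", "FN_PD", "FN_DD"}

    def test_subgroup_means_match_direct_recount(self):
        df = synthetic_table(seed=12, signal=True)
        X, y, meta = make_task_dataset(df, TASKS["Task3"])
        cv = run_cv(X, y, ModelConfig(seed=12))
        table = error_analysis(cv, meta, TASKS["Task3"]).set_index("error_class")
        fn_ids = [i for i in meta.index
                  if cv.y[i] == 1 and cv.oof_prediction[i] == 0]
        assert table.loc["FN", "count"] == len(fn_ids)
        if fn_ids:
            assert table.loc["FN", "mean_age"] == pytest.approx(
                meta.loc[fn_ids, "age"].mean())
            assert table.loc["FN", "mean_hoehn_yahr"] == pytest.approx(
                meta.loc[fn_ids, "hoehn_yahr"].dropna().mean())


class TestModelObjects:
    def test_summary_reports_task_and_metrics(self):
        results = TaskClassifier(synthetic_table(), "Task1",
                                 config=ModelConfig(seed=0)).fit()
        text = results.summary()
        assert "Task1" in text and "accuracy" in text and "baseline" in text

    def test_from_cohort_constructor(self, small_cohort):
        results = TaskClassifier.from_cohort(small_cohort, "Task1",
                                             config=ModelConfig(seed=0)).fit()
        assert 0.0 <= results.accuracy <= 1.0
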