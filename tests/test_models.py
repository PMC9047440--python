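import numpy as np
import pandas as pd
import pytest

from mrmprep.chromatogram import PeakCandidate
from mrmprep.models import (
    LabelingError,
    TrainingExample,
    derive_picking_labels,
    derive_reporting_labels,
    f1_from_counts,
    fallback_score,
    feature_importance,
    load_model,
    predict_score,
    save_model,
    train_classifier,
)


def blob_examples(n=500, seed=1, informative=(0, 1), noise_feature=None):
    """Two well-separated Gaussian blobs in QS space (separable fixture)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.4, 0.6, size=(n, 20))
    y = rng.integers(0, 2, size=n)
    for f in informative:
        X[:, f] = np.where(y == 1, 0.9, 0.1) + rng.normal(0, 0.02, n)
    if noise_feature is not None:
        X[:, noise_feature] = rng.uniform(0, 1, n)
    X = np.clip(X, 0, 1)
    return [TrainingExample(features=x, label=int(t)) for x, t in zip(X, y)]


def candidate(metab, sample, apex_time, qs=None):
    return PeakCandidate(
        metabolite=metab, sample_id=sample, apex_idx=0,
        apex_time=apex_time, start_time=apex_time - 1, end_time=apex_time + 1,
        height=1.0, area=1.0,
        qs=qs if qs is not None else np.full(20, 0.5),
    )


class TestPickingLabels:
    SOLUTION = pd.DataFrame(
        [{"metabolite": "m", "sample": "s", "area": 1000.0, "start": 2.4,
          "end": 2.7}]
    )

    def test_apex_inside_solution_borders_is_positive(self):
        ex = derive_picking_labels([candidate("m", "s", 2.5)], self.SOLUTION)
        assert ex[0].label == 1

    def test_apex_outside_borders_is_negative(self):
        ex = derive_picking_labels([candidate("m", "s", 2.2)], self.SOLUTION)
        assert ex[0].label == 0

    def test_zero_area_marks_all_candidates_negative(self):
        sol = self.SOLUTION.assign(area=0.0)
        exs = derive_picking_labels(
            [candidate("m", "s", 2.5), candidate("m", "s", 2.6)], sol
        )
        assert [e.label for e in exs] == [0, 0]

    def test_uncovered_candidate_rejected(self):
        with pytest.raises(LabelingError, match="other"):
            derive_picking_labels([candidate("other", "s", 2.5)], self.SOLUTION)


class TestReportingLabels:
    def test_two_maps_to_one_zero_maps_to_zero_one_excluded(self):
        sol = pd.DataFrame(
            [
                {"metabolite": "m", "sample": f"s{i}", "value": v}
                for i, v in enumerate([2, 1, 0])
            ]
        )
        feats = {("m", f"s{i}"): np.zeros(26) for i in range(3)}
        exs = derive_reporting_labels(feats, sol)
        assert [(e.sample_id, e.label) for e in exs] == [("s0", 1), ("s2", 0)]

    def test_all_excluded_yields_empty_set(self):
        sol = pd.DataFrame([{"metabolite": "m", "sample": "s", "value": 1}])
        assert derive_reporting_labels({("m", "s"): np.zeros(26)}, sol) == []

    def test_invalid_value_rejected_with_cell(self):
        sol = pd.DataFrame([{"metabolite": "m", "sample": "s", "value": 3}])
        with pytest.raises(LabelingError, match=r"\('?m'?, ?'?s'?\)|m, s"):
            derive_reporting_labels({("m", "s"): np.zeros(26)}, sol)


class TestTrainClassifier:
    def test_separable_fixture_reaches_perfect_f1(self):
        model = train_classifier(blob_examples(), "random_forest", seed=1)
        assert model.validation_f1 == 1.0
        assert model.task == "picking"
        assert set(model.tuned_hyperparams) == {"n_estimators", "max_depth"}

    def test_shuffled_labels_score_near_chance(self):
        examples = blob_examples(seed=1)
        rng = np.random.default_rng(1)
        labels = rng.permutation([e.label for e in examples])
        shuffled = [
            TrainingExample(features=e.features, label=int(l))
            for e, l in zip(examples, labels)
        ]
        model = train_classifier(shuffled, "random_forest", seed=1)
        assert model.validation_f1 < 0.7

    def test_same_seed_is_deterministic(self):
        a = train_classifier(blob_examples(), "random_forest", seed=5)
        b = train_classifier(blob_examples(), "random_forest", seed=5)
        assert a.validation_f1 == b.validation_f1
        X = np.vstack([e.features for e in blob_examples(n=50, seed=9)])
        np.testing.assert_array_equal(predict_score(a, X), predict_score(b, X))

    def test_single_class_rejected(self):
        ones = [TrainingExample(np.full(20, 0.5), 1) for _ in range(30)]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ones, "random_forest")

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            train_classifier(blob_examples(n=10), "random_forest")

    @pytest.mark.parametrize(
        "algorithm", ["gradient_boosted_trees", "svm", "neural_net"]
    )
    def test_alternative_algorithms_learn_the_separable_fixture(self, algorithm):
        model = train_classifier(blob_examples(n=200), algorithm, seed=1)
        assert model.validation_f1 >= 0.9
        scores = predict_score(
            model, np.vstack([e.features for e in blob_examples(n=40, seed=2)])
        )
        assert np.all((scores >= 0) & (scores <= 1))


class TestPredictScore:
    def test_true_class_scores_high_on_training_fixture(self):
        examples = blob_examples()
        model = train_classifier(examples, "random_forest", seed=1)
        pos = next(e for e in examples if e.label == 1)
        neg = next(e for e in examples if e.label == 0)
        assert predict_score(model, pos.features) > 0.9
        assert predict_score(model, neg.features) < 0.1

    def test_length_mismatch_rejected(self):
        model = train_classifier(blob_examples(), "random_forest", seed=1)
        with pytest.raises(ValueError, match="expects 20"):
            predict_score(model, np.zeros(26))


class TestFallbackScore:
    @pytest.mark.parametrize(
        "qs,expected",
        [
            (np.ones(20), 1.0),
            (np.full(20, 0.5), 0.5),
            (np.array([1.0] * 10 + [0.0] * 10), 0.5),
        ],
    )
    def test_mean_of_scores(self, qs, expected):
        assert fallback_score(qs) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            fallback_score(np.ones(19))


class TestF1:
    def test_published_confusion_counts(self):
        # TP/FP/FN column of the best-performing tool in the comparison
        assert f1_from_counts(887, 1, 70) == pytest.approx(0.9615, abs=1e-4)

    def test_perfect_counts(self):
        assert f1_from_counts(10, 0, 0) == 1.0

    def test_no_true_positives(self):
        assert f1_from_counts(0, 5, 5) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            f1_from_counts(0, 0, 0)


class TestFeatureImportance:
    def test_normalized_and_sorted(self):
        model = train_classifier(blob_examples(), "random_forest", seed=1)
        imp = feature_importance(model)
        values = list(imp.values())
        assert sum(values) == pytest.approx(1.0, abs=1e-9)
        assert values == sorted(values, reverse=True)

    def test_noise_feature_ranks_below_informative(self):
        model = train_classifier(
            blob_examples(informative=(0, 1), noise_feature=5),
            "random_forest", seed=1,
        )
        imp = feature_importance(model)
        names = list(imp)
        from mrmprep.quality import QS_NAMES

        assert names.index(QS_NAMES[5]) > max(
            names.index(QS_NAMES[0]), names.index(QS_NAMES[1])
        )

    def test_constant_feature_has_zero_importance(self):
        examples = blob_examples()
        for e in examples:
            e.features[7] = 0.5
        model = train_classifier(examples, "random_forest", seed=1)
        from mrmprep.quality import QS_NAMES

        assert feature_importance(model)[QS_NAMES[7]] == 0.0

    def test_svm_unsupported(self):
        model = train_classifier(blob_examples(n=100), "svm", seed=1)
        with pytest.raises(TypeError):
            feature_importance(model)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = train_classifier(blob_examples(), "random_forest", seed=1)
        path = save_model(model, tmp_path / "picking.joblib")
        loaded = load_model(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.validation_f1 == model.validation_f1
        X = np.vstack([e.features for e in blob_examples(n=64, seed=3)])
        np.testing.assert_array_equal(
            predict_score(loaded, X), predict_score(model, X)
        )

    def test_foreign_artifact_rejected(self, tmp_path):
        import joblib

        p = tmp_path / "other.joblib"
        joblib.dump({"hello": 1}, p)
        with pytest.raises(ValueError):
            load_model(p)
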