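"""Hold-out splitting, task-model training, window merging and metrics."""

import numpy as np
import pytest

from tricadence import (
    ConfusionReport,
    StftConfig,
    evaluate_binary,
    load_model,
    merge_windows,
    predict_windows,
    save_model,
    split_holdout,
    train_task_model,
)
from tricadence.benchmarks import build_rider_cohort
from tricadence.classifier import WindowSet


def toy_sessions(rng, participants=("p1", "p2", "p3"), n_windows=100, n_features=8):
    """Synthetic spectrally separated two-class sessions: class decides which
    feature block carries energy."""
    sessions = {}
    for pid in participants:
        labels = rng.choice(["in_saddle", "out_of_saddle"], size=n_windows)
        X = rng.normal(0.0, 0.1, size=(n_windows, n_features))
        X[labels == "in_saddle", :4] += 5.0
        X[labels == "out_of_saddle", 4:] += 5.0
        sessions[pid] = (X, labels)
    return sessions


@pytest.fixture
def sessions(rng):
    return toy_sessions(rng)


class TestSplitHoldout:
    def test_eighty_twenty_split(self, sessions):
        train, test, gen = split_holdout(sessions, {"p1"}, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert len(gen) == 200

    def test_non_train_participant_contributes_nothing(self, sessions):
        train, _, _ = split_holdout(sessions, {"p1", "p2"}, seed=0)
        assert "p3" not in set(train.participants)

    def test_partition_property(self, sessions):
        train, test, gen = split_holdout(sessions, {"p1", "p3"}, seed=3)
        keys = []
        for ws in (train, test, gen):
            keys += list(zip(ws.participants, ws.window_starts_s))
        assert len(keys) == len(set(keys)) == 300

    def test_empty_train_ids_rejected(self, sessions):
        with pytest.raises(ValueError):
            split_holdout(sessions, set(), seed=0)

    def test_blocks_are_contiguous(self, sessions):
        # each participant's test windows form whole contiguous blocks of 10
        _, test, _ = split_holdout(sessions, {"p1"}, seed=5)
        starts = np.sort(test.window_starts_s)
        runs = np.split(starts, np.where(np.diff(starts) > 1.5)[0] + 1)
        assert all(len(r) % 10 == 0 for r in runs)


class TestTrainPredict:
    def test_separable_classes_learned_perfectly(self, sessions):
        train, test, _ = split_holdout(sessions, {"p1", "p2"}, seed=0)
        model = train_task_model(train, seed=0)
        assert np.mean(predict_windows(model, train.features) == train.labels) == 1.0
        assert np.mean(predict_windows(model, test.features) == test.labels) >= 0.95

    def test_same_seed_reproduces_predictions(self, sessions):
        train, test, _ = split_holdout(sessions, {"p1", "p2"}, seed=0)
        p1 = predict_windows(train_task_model(train, seed=11), test.features)
        p2 = predict_windows(train_task_model(train, seed=11), test.features)
        assert np.array_equal(p1, p2)

    def test_permuted_labels_give_chance_accuracy(self, rng, sessions):
        train, _, gen = split_holdout(sessions, {"p1", "p2"}, seed=0)
        shuffled = WindowSet(
            train.features,
            rng.permutation(train.labels),
            train.participants,
            train.window_starts_s,
        )
        model = train_task_model(shuffled, seed=0)
        acc = np.mean(predict_windows(model, gen.features) == gen.labels)
        majority = max(np.mean(gen.labels == c) for c in set(gen.labels))
        assert acc <= majority + 0.10

    def test_single_class_training_rejected(self, sessions):
        train, _, _ = split_holdout(sessions, {"p1"}, seed=0)
        only_in = train.subset(train.labels == "in_saddle")
        with pytest.raises(ValueError, match="class"):
            train_task_model(only_in, seed=0)

    def test_dimension_mismatch_rejected(self, sessions, rng):
        train, _, _ = split_holdout(sessions, {"p1"}, seed=0)
        model = train_task_model(train, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict_windows(model, rng.normal(size=(4, 5)))

    def test_model_round_trip_through_bundle(self, sessions, tmp_path):
        train, test, _ = split_holdout(sessions, {"p1", "p2"}, seed=0)
        model = train_task_model(train, seed=0)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.classes == model.classes
        assert np.array_equal(
            predict_windows(back, test.features), predict_windows(model, test.features)
        )


class TestMergeWindows:
    def test_runs_become_intervals(self):
        labels = ["in_saddle", "in_saddle", "out_of_saddle", "out_of_saddle", "in_saddle"]
        track = merge_windows(labels, StftConfig())
        assert track.intervals == [
            (0.0, 5.0, "in_saddle"),
            (5.0, 10.0, "out_of_saddle"),
            (10.0, 12.5, "in_saddle"),
        ]

    def test_uniform_labels_merge_to_one_interval(self):
        track = merge_windows(["coasting"] * 8, StftConfig())
        assert track.intervals == [(0.0, 20.0, "coasting")]

    def test_alternating_labels_one_interval_per_window(self):
        labels = ["in_saddle", "out_of_saddle"] * 4
        assert len(merge_windows(labels, StftConfig())) == 8

    def test_unlabelled_runs_become_gaps(self):
        track = merge_windows(["in_saddle", "unlabelled", "coasting"], StftConfig())
        assert [iv[2] for iv in track.intervals] == ["in_saddle", "coasting"]


class TestEvaluateBinary:
    def test_perfect_prediction(self):
        truth = ["in_saddle", "out_of_saddle", "in_saddle"]
        report = evaluate_binary(truth, truth)
        assert report.sensitivity_pct == 100.0 and report.specificity_pct == 100.0

    def test_all_negative_prediction_has_zero_sensitivity(self):
        truth = ["in_saddle", "out_of_saddle"]
        report = evaluate_binary(["in_saddle", "in_saddle"], truth)
        assert report.sensitivity_pct == 0.0

    def test_hand_computed_confusion(self):
        report = ConfusionReport(tp=42, fn=58, tn=96, fp=4)
        assert report.sensitivity_pct == pytest.approx(42.0)
        assert report.specificity_pct == pytest.approx(96.0)
        assert report.accuracy_pct == pytest.approx(69.0)
        assert report.total == 200

    def test_coasting_truth_windows_excluded(self):
        pred = ["out_of_saddle", "in_saddle", "coasting"]
        truth = ["coasting", "coasting", "coasting"]
        assert evaluate_binary(pred, truth).total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_binary(["in_saddle"], ["in_saddle", "in_saddle"])


class TestEndToEndCohort:
    def test_rider_cohort_windows_fully_labelled(self):
        sessions = build_rider_cohort(base_seed=5, n_balanced=1, n_race=1,
                                      duration_s=300.0)
        for fm, labels in sessions.values():
            assert fm.n_windows == len(labels)
            assert "unlabelled" not in set(labels)
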