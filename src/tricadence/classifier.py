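"""Cycling-task classification from windowed spectral features.

A gradient-boosted decision-tree ensemble (XGBoost, default parameters —
deliberately untuned proof of concept) distinguishes ``in_saddle``,
``out_of_saddle`` and ``coasting`` windows. Evaluation follows a hold-out
protocol at the participant level: for a designated set of training
participants, 80% of each session's windows (in contiguous, seeded-order
blocks, to limit temporal leakage between adjacent windows) train the model
and the remaining 20% test it; every window of the remaining participants
forms a generalisation set the model never sees during training.

The headline metrics treat ``out_of_saddle`` as the positive class:
sensitivity is the rate at which out-of-saddle windows are recognised,
specificity the rate at which in-saddle windows are retained. Coasting
truth windows are excluded from this binary report, since separating
coasting from seated pedalling is not claimed.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from xgboost import XGBClassifier

from .features import FeatureMatrix, Standardizer, StftConfig, fit_standardizer
from .types import (
    LABEL_IN_SADDLE,
    LABEL_OUT_OF_SADDLE,
    UNLABELLED,
    LabelTrack,
    labels_to_track,
)

__all__ = [
    "WindowSet",
    "TrainedTaskModel",
    "ConfusionReport",
    "split_holdout",
    "train_task_model",
    "predict_windows",
    "merge_windows",
    "evaluate_binary",
    "save_model",
    "load_model",
]


@dataclass
class WindowSet:
    """A bag of windows: features, labels, and their provenance."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) label strings
    participants: np.ndarray  # (n,) participant ids
    window_starts_s: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.features[mask],
            self.labels[mask],
            self.participants[mask],
            self.window_starts_s[mask],
        )

    def for_participant(self, pid) -> "WindowSet":
        return self.subset(self.participants == pid)


def _empty_window_set(n_features: int) -> WindowSet:
    return WindowSet(
        np.empty((0, n_features)),
        np.empty(0, dtype=object),
        np.empty(0, dtype=object),
        np.empty(0),
    )


def split_holdout(
    sessions: Mapping,
    train_ids: Iterable,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_blocks: int = 10,
) -> Tuple[WindowSet, WindowSet, WindowSet]:
    """Participant-level hold-out split.

    ``sessions`` maps participant id -> ``(FeatureMatrix, labels)``. Windows
    of each training participant are divided into ``n_blocks`` contiguous
    blocks whose order is shuffled with ``seed``; blocks fill the training
    set until it holds ``train_fraction`` of that participant's windows and
    the rest become the test set. All windows of other participants form the
    generalisation set. The three sets partition the windows exactly.
    """
    train_ids = set(train_ids)
    if not train_ids:
        raise ValueError("train_ids must not be empty")
    unknown = train_ids - set(sessions)
    if unknown:
        raise ValueError(f"train_ids not present in sessions: {sorted(map(str, unknown))}")
    rng = np.random.default_rng(seed)
    parts: Dict[str, list] = {"train": [], "test": [], "gen": []}
    for pid in sessions:  # insertion order: deterministic
        fm, labels = sessions[pid]
        values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
        starts = (
            fm.window_starts_s
            if isinstance(fm, FeatureMatrix)
            else np.arange(values.shape[0], dtype=float)
        )
        labels = np.asarray(labels, dtype=object)
        n = values.shape[0]
        if labels.shape[0] != n:
            raise ValueError(f"participant {pid!r}: {n} windows but {labels.shape[0]} labels")
        pids = np.full(n, pid, dtype=object)
        if pid not in train_ids:
            parts["gen"].append((values, labels, pids, starts))
            continue
        blocks = np.array_split(np.arange(n), min(n_blocks, max(n, 1)))
        order = rng.permutation(len(blocks))
        goal = int(round(train_fraction * n))
        train_idx: list = []
        test_idx: list = []
        for b in order:
            target = train_idx if len(train_idx) < goal else test_idx
            target.extend(blocks[b].tolist())
        tr = np.asarray(sorted(train_idx), dtype=int)
        te = np.asarray(sorted(test_idx), dtype=int)
        parts["train"].append((values[tr], labels[tr], pids[tr], starts[tr]))
        parts["test"].append((values[te], labels[te], pids[te], starts[te]))

    def _cat(chunks, n_features):
        if not chunks:
            return _empty_window_set(n_features)
        return WindowSet(
            np.concatenate([c[0] for c in chunks]),
            np.concatenate([c[1] for c in chunks]),
            np.concatenate([c[2] for c in chunks]),
            np.concatenate([c[3] for c in chunks]),
        )

    d = next(iter(sessions.values()))
    n_features = (
        d[0].values.shape[1] if isinstance(d[0], FeatureMatrix) else np.asarray(d[0]).shape[1]
    )
    return tuple(_cat(parts[k], n_features) for k in ("train", "test", "gen"))


@dataclass
class TrainedTaskModel:
    """Fitted ensemble plus everything needed to apply it to raw features."""

    booster: XGBClassifier
    standardizer: Standardizer
    classes: tuple
    seed: int
    stft: StftConfig = StftConfig()


def train_task_model(
    train: WindowSet,
    classes: Optional[Sequence[str]] = None,
    seed: int = 0,
    stft: StftConfig = StftConfig(),
) -> TrainedTaskModel:
    """Train the gradient-boosted task classifier on a training window set.

    ``unlabelled`` windows are dropped. The standardizer is fitted on the
    training windows only. Training is deterministic for a fixed seed
    (single-threaded ensemble). Raises if fewer than two classes remain.
    """
    keep = train.labels != UNLABELLED
    X = train.features[keep]
    y = train.labels[keep]
    present = sorted(set(y.tolist()))
    if classes is None:
        classes = present
    else:
        classes = sorted(classes)
        missing = set(present) - set(classes)
        if missing:
            raise ValueError(f"training labels outside the class set: {sorted(missing)}")
    if len(present) < 2:
        raise ValueError(
            f"training data contain {len(present)} class(es); need at least two"
        )
    standardizer = fit_standardizer(X)
    Xz = standardizer.transform(X)
    index = {c: i for i, c in enumerate(classes)}
    y_enc = np.asarray([index[c] for c in y], dtype=int)
    clf = XGBClassifier(random_state=seed, n_jobs=1)
    clf.fit(Xz, y_enc)
    return TrainedTaskModel(
        booster=clf,
        standardizer=standardizer,
        classes=tuple(classes),
        seed=seed,
        stft=stft,
    )


def predict_windows(model: TrainedTaskModel, features) -> np.ndarray:
    """Predict one task label per window; standardisation happens inside."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    Xz = model.standardizer.transform(values)
    pred = model.booster.predict(Xz)
    return np.asarray([model.classes[int(i)] for i in pred], dtype=object)


def merge_windows(window_labels: Sequence[str], cfg: StftConfig = StftConfig()) -> LabelTrack:
    """Run-length encode per-window labels into a task interval track.

    Maximal runs of identical labels become half-open intervals whose
    durations are multiples of the window hop; ``unlabelled`` runs become
    gaps. Coasting-duration validation is relaxed: a predicted single-window
    coasting run is a legitimate model output.
    """
    return labels_to_track(list(window_labels), cfg.hop_s, enforce_min_coasting=False)


@dataclass
class ConfusionReport:
    """Window-level confusion counts with ``out_of_saddle`` positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity_pct(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def specificity_pct(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
        }


def evaluate_binary(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionReport:
    """Binary in-saddle vs out-of-saddle confusion report.

    Windows whose truth label is neither ``in_saddle`` nor ``out_of_saddle``
    (coasting, unlabelled) are excluded. A prediction other than
    ``out_of_saddle`` counts as negative.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"prediction ({predicted.shape}) and truth ({truth.shape}) lengths differ"
        )
    keep = (truth == LABEL_IN_SADDLE) | (truth == LABEL_OUT_OF_SADDLE)
    p = predicted[keep] == LABEL_OUT_OF_SADDLE
    t = truth[keep] == LABEL_OUT_OF_SADDLE
    return ConfusionReport(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def save_model(model: TrainedTaskModel, path) -> None:
    """Persist a trained model as a single JSON bundle."""
    with tempfile.TemporaryDirectory() as tmp:
        booster_path = os.path.join(tmp, "booster.json")
        # newer scikit-learn drops `_estimator_type`, which xgboost's
        # persistence still validates; pin it on the instance
        model.booster._estimator_type = "classifier"
        model.booster.save_model(booster_path)
        with open(booster_path) as fh:
            booster_json = json.load(fh)
    bundle = {
        "format": "tricadence-task-model-v1",
        "classes": list(model.classes),
        "seed": model.seed,
        "standardizer": model.standardizer.to_dict(),
        "stft": {
            "window_samples": model.stft.window_samples,
            "overlap_samples": model.stft.overlap_samples,
            "sample_rate_hz": model.stft.sample_rate_hz,
            "prefilter_band": list(model.stft.prefilter_band)
            if model.stft.prefilter_band
            else None,
            "prefilter_order": model.stft.prefilter_order,
        },
        "booster": booster_json,
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_model(path) -> TrainedTaskModel:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format") != "tricadence-task-model-v1":
        raise ValueError(f"{path} is not a tricadence task-model bundle")
    clf = XGBClassifier()
    clf._estimator_type = "classifier"
    with tempfile.TemporaryDirectory() as tmp:
        booster_path = os.path.join(tmp, "booster.json")
        with open(booster_path, "w") as fh:
            json.dump(bundle["booster"], fh)
        clf.load_model(booster_path)
    stft_d = bundle["stft"]
    stft = StftConfig(
        window_samples=stft_d["window_samples"],
        overlap_samples=stft_d["overlap_samples"],
        sample_rate_hz=stft_d["sample_rate_hz"],
        prefilter_band=tuple(stft_d["prefilter_band"]) if stft_d["prefilter_band"] else None,
        prefilter_order=stft_d["prefilter_order"],
    )
    return TrainedTaskModel(
        booster=clf,
        standardizer=Standardizer.from_dict(bundle["standardizer"]),
        classes=tuple(bundle["classes"]),
        seed=int(bundle["seed"]),
        stft=stft,
    )
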