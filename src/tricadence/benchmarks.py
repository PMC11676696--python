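"""End-to-end benchmark experiments on synthetic sessions.

These drive the full pipelines — generation, detection, feature extraction,
training, evaluation — at the generator's default difficulty and report the
same summary metrics the tool produces on field data: mean detection
accuracy and per-epoch cadence RMSE per discipline, and mean window-level
accuracy/specificity of the cycling-task classifier under the
participant-level hold-out protocol.

Session seeds are derived deterministically from one base seed so a whole
experiment is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .cadence import (
    CadenceSeries,
    cadence_rmse,
    cadence_series,
    count_accuracy,
    default_profiles,
    detect_events,
)
from .classifier import (
    ConfusionReport,
    WindowSet,
    evaluate_binary,
    predict_windows,
    split_holdout,
    train_task_model,
)
from .features import StftConfig, align_labels, stft_magnitudes
from .synthetic import (
    SyntheticSessionSpec,
    balanced_schedule,
    race_schedule,
    simulate_cycling_session,
    simulate_discipline,
)
from .types import fine_grain_labels

__all__ = [
    "CadenceBenchmarkResult",
    "ClassifierBenchmarkResult",
    "session_seed",
    "run_cadence_benchmark",
    "run_classifier_benchmark",
]

#: Study-condition defaults per discipline: (n_sessions, duration_s,
#: cadence range events/min).
CADENCE_CONDITIONS = {
    "swim": {"n_sessions": 6, "duration_s": 480.0, "cadence_range": (71.0, 87.0)},
    "cycle": {"n_sessions": 5, "duration_s": 900.0, "cadence_range": (150.0, 165.0)},
    "run": {"n_sessions": 6, "duration_s": 600.0, "cadence_range": (166.0, 178.0)},
}

RMSE_EPOCH_S = 60.0


def session_seed(base_seed: int, index: int) -> int:
    """Deterministic per-session seed derived from one base seed."""
    return int((base_seed * 10_007 + index) % 2**31)


@dataclass
class CadenceBenchmarkResult:
    discipline: str
    accuracies_pct: np.ndarray
    rmses_per_min: np.ndarray
    detected_totals: np.ndarray
    truth_totals: np.ndarray

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def mean_rmse_per_min(self) -> float:
        return float(np.mean(self.rmses_per_min))


def _drop_partial_epoch(series: CadenceSeries, duration_s: float) -> CadenceSeries:
    """Drop a trailing partial epoch from RMSE computation (totals keep it)."""
    full = int(duration_s // series.epoch_s)
    return CadenceSeries(
        series.epoch_starts_s[:full], series.counts[:full], series.epoch_s
    )


def run_cadence_benchmark(
    discipline: str,
    base_seed: int = 1,
    n_sessions: Optional[int] = None,
    duration_s: Optional[float] = None,
    cadence_range: Optional[Tuple[float, float]] = None,
) -> CadenceBenchmarkResult:
    """Peak-counting benchmark for one discipline.

    Generates ``n_sessions`` synthetic sessions with cadences evenly spaced
    over ``cadence_range`` and generator-default amplitudes and noise, runs
    the discipline's detection profile, and compares against exact ground
    truth: per-session count accuracy and 60 s-epoch cadence RMSE.
    """
    cond = CADENCE_CONDITIONS[discipline]
    n_sessions = n_sessions or cond["n_sessions"]
    duration_s = duration_s or cond["duration_s"]
    cadence_range = cadence_range or cond["cadence_range"]
    profile = default_profiles()[discipline]
    cadences = np.linspace(*cadence_range, n_sessions)
    acc, rmse, det_tot, tru_tot = [], [], [], []
    for i, cad in enumerate(cadences):
        spec = SyntheticSessionSpec(
            discipline=discipline,
            duration_s=duration_s,
            cadence_per_min=float(cad),
            seed=session_seed(base_seed, i),
        )
        rec, truth = simulate_discipline(spec)
        detected = detect_events(rec, profile)
        acc.append(count_accuracy(len(detected), truth.event_count))
        det = _drop_partial_epoch(
            cadence_series(detected, RMSE_EPOCH_S, duration_s), duration_s
        )
        tru = _drop_partial_epoch(
            truth.true_cadence_series(RMSE_EPOCH_S, duration_s), duration_s
        )
        rmse.append(cadence_rmse(det, tru))
        det_tot.append(len(detected))
        tru_tot.append(truth.event_count)
    return CadenceBenchmarkResult(
        discipline=discipline,
        accuracies_pct=np.asarray(acc),
        rmses_per_min=np.asarray(rmse),
        detected_totals=np.asarray(det_tot, dtype=int),
        truth_totals=np.asarray(tru_tot, dtype=int),
    )


@dataclass
class ClassifierBenchmarkResult:
    per_rider: Dict[str, ConfusionReport]
    train_ids: Tuple[str, ...]

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean([r.accuracy_pct for r in self.per_rider.values()]))

    @property
    def mean_specificity_pct(self) -> float:
        return float(np.mean([r.specificity_pct for r in self.per_rider.values()]))

    @property
    def mean_sensitivity_pct(self) -> float:
        return float(np.mean([r.sensitivity_pct for r in self.per_rider.values()]))


def _rider_windows(
    spec: SyntheticSessionSpec, cfg: StftConfig
) -> Tuple[np.ndarray, np.ndarray]:
    rec, truth = simulate_cycling_session(spec)
    features = stft_magnitudes(rec, cfg)
    fine = fine_grain_labels(truth.label_track, 0.1, spec.duration_s)
    labels = align_labels(fine, cfg, n_windows=features.n_windows)
    return features, labels


def build_rider_cohort(
    base_seed: int = 1,
    n_balanced: int = 6,
    n_race: int = 6,
    duration_s: float = 1200.0,
    cfg: StftConfig = StftConfig(),
    race_effort_s: Tuple[float, float] = (20.0, 20.0),
    race_quantum: Optional[float] = 2.5,
) -> Dict[str, Tuple]:
    """Twelve synthetic riders: half with balanced equal 20 s task blocks,
    half with long seated stretches containing standing efforts of
    ``race_effort_s`` duration. ``race_quantum`` rounds race-schedule block
    durations to the STFT window grid; pass ``None`` for unaligned blocks
    (the uncontrolled first-round collection style)."""
    sessions = {}
    for i in range(n_balanced):
        n_rep = int(duration_s // 60)
        spec = SyntheticSessionSpec(
            discipline="cycle",
            duration_s=n_rep * 60.0,
            task_schedule=balanced_schedule(n_rep),
            seed=session_seed(base_seed, 100 + i),
        )
        sessions[f"balanced_{i + 1}"] = _rider_windows(spec, cfg)
    for i in range(n_race):
        seed = session_seed(base_seed, 200 + i)
        sched = race_schedule(
            duration_s, seed=seed, effort_s=race_effort_s, quantum=race_quantum
        )
        spec = SyntheticSessionSpec(
            discipline="cycle", duration_s=duration_s, task_schedule=sched, seed=seed
        )
        sessions[f"race_{i + 1}"] = _rider_windows(spec, cfg)
    return sessions


def run_classifier_benchmark(
    base_seed: int = 1,
    duration_s: float = 1200.0,
    cfg: StftConfig = StftConfig(),
    race_effort_s: Tuple[float, float] = (20.0, 20.0),
    race_quantum: Optional[float] = 2.5,
) -> ClassifierBenchmarkResult:
    """Hold-out classification benchmark across twelve synthetic riders.

    Three balanced-schedule and three race-style riders are designated as
    training participants; their windows are split 80/20 into contiguous
    blocks for train/test. The model predicts every rider's windows, and
    each rider's binary in-saddle vs out-of-saddle confusion report is
    computed on their evaluation windows: the held-out 20% for training
    riders, the full session for excluded riders. Coasting truth windows
    are excluded throughout.
    """
    sessions = build_rider_cohort(
        base_seed,
        duration_s=duration_s,
        cfg=cfg,
        race_effort_s=race_effort_s,
        race_quantum=race_quantum,
    )
    train_ids = ("balanced_1", "balanced_2", "balanced_3", "race_1", "race_2", "race_3")
    train, test, gen = split_holdout(sessions, train_ids, seed=base_seed)
    model = train_task_model(train, seed=base_seed, stft=cfg)
    per_rider: Dict[str, ConfusionReport] = {}
    for pid in sessions:
        ws: WindowSet = (test if pid in train_ids else gen).for_participant(pid)
        pred = predict_windows(model, ws.features)
        per_rider[pid] = evaluate_binary(pred, ws.labels)
    return ClassifierBenchmarkResult(per_rider=per_rider, train_ids=train_ids)
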