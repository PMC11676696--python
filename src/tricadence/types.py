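"""Shared data model for trunk-IMU triathlon recordings.

A recording holds six inertial channels sampled uniformly at ``sample_rate_hz``
(default 100 Hz): tri-axial acceleration in g and tri-axial angular velocity in
degrees per second, plus an optional 10 Hz GPS sub-track. The axis convention
is fixed project-wide: x = forward (direction of travel), y = mediolateral,
z = vertical (gravity-aligned at rest).

Cycling-task annotations live in a :class:`LabelTrack` — an ordered list of
non-overlapping ``[start, end)`` intervals labelled ``in_saddle``,
``out_of_saddle`` or ``coasting``. Coasting is defined as riding without
turning the pedals for more than one second, so coasting intervals shorter
than that are rejected. Gaps between intervals are permitted and surface as
the sentinel label ``unlabelled`` when the track is rasterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LABEL_IN_SADDLE",
    "LABEL_OUT_OF_SADDLE",
    "LABEL_COASTING",
    "UNLABELLED",
    "TASK_LABELS",
    "CHANNEL_NAMES",
    "ValidationError",
    "TableFormatError",
    "GpsTrack",
    "ImuRecording",
    "LabelTrack",
    "fine_grain_labels",
]

LABEL_IN_SADDLE = "in_saddle"
LABEL_OUT_OF_SADDLE = "out_of_saddle"
LABEL_COASTING = "coasting"
#: Sentinel for timeline portions not covered by any labelled interval.
UNLABELLED = "unlabelled"
TASK_LABELS = frozenset({LABEL_IN_SADDLE, LABEL_OUT_OF_SADDLE, LABEL_COASTING})

#: Fixed channel order used everywhere (tables, feature matrices, selectors).
CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

ACC_RANGE_G = 16.0
GYR_RANGE_DPS = 2000.0
MIN_COASTING_S = 1.0


class ValidationError(ValueError):
    """Raised when data violate a model invariant."""


class TableFormatError(ValueError):
    """Raised when an input table is structurally malformed."""


@dataclass
class GpsTrack:
    """A 10 Hz latitude/longitude track aligned to the recording clock."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.t) == len(self.lat) == len(self.lon)):
            raise ValidationError("GPS track columns must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("GPS timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ImuRecording:
    """Uniformly sampled 6-channel inertial time series with optional GPS."""

    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray
    gyr_y: np.ndarray
    gyr_z: np.ndarray
    sample_rate_hz: float = 100.0
    gps: Optional[GpsTrack] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t",) + tuple(CHANNEL_NAMES):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        for name in CHANNEL_NAMES:
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(
                    f"time column is not strictly increasing at row {row}"
                )
            expected = 1.0 / self.sample_rate_hz
            if np.max(np.abs(dt - expected)) > 1e-6:
                row = int(np.argmax(np.abs(dt - expected) > 1e-6)) + 1
                raise ValidationError(
                    f"non-uniform sampling at row {row}: spacing deviates from "
                    f"1/{self.sample_rate_hz} Hz by more than 1e-6 s"
                )
        for name in ("acc_x", "acc_y", "acc_z"):
            self._check_range(name, ACC_RANGE_G, "g")
        for name in ("gyr_x", "gyr_y", "gyr_z"):
            self._check_range(name, GYR_RANGE_DPS, "deg/s")
        if self.gps is not None and len(self.gps) and n:
            if self.gps.t[0] < self.t[0] - 1e-9 or self.gps.t[-1] > self.t[-1] + 1e-9:
                raise ValidationError(
                    "GPS timestamps fall outside the inertial time span"
                )

    def _check_range(self, name: str, limit: float, unit: str) -> None:
        x = getattr(self, name)
        bad = np.abs(x) > limit
        if np.any(bad):
            row = int(np.argmax(bad))
            raise ValidationError(
                f"{name} out of range at row {row}: |{x[row]:g}| > {limit:g} {unit}"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return one inertial channel by name (e.g. ``"acc_z"``)."""
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        return getattr(self, name)

    def channel_matrix(self) -> np.ndarray:
        """All six channels as an (N, 6) array in canonical order."""
        return np.column_stack([getattr(self, c) for c in CHANNEL_NAMES])


@dataclass
class LabelTrack:
    """Ordered, non-overlapping cycling-task intervals.

    Intervals are half-open ``[start, end)``: a boundary instant belongs to
    the later interval. Set ``enforce_min_coasting=False`` only for fixtures
    that deliberately violate the >1 s coasting rule.
    """

    intervals: list
    enforce_min_coasting: bool = True

    def __post_init__(self) -> None:
        cleaned = []
        for iv in self.intervals:
            start, end, label = iv
            cleaned.append((float(start), float(end), str(label)))
        cleaned.sort(key=lambda iv: iv[0])
        self.intervals = cleaned
        self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for start, end, label in self.intervals:
            if label not in TASK_LABELS:
                raise TableFormatError(
                    f"unknown task label {label!r}; expected one of {sorted(TASK_LABELS)}"
                )
            if end <= start:
                raise ValidationError(f"interval ({start}, {end}) has non-positive duration")
            if start < prev_end - 1e-12:
                raise ValidationError(
                    f"interval starting at {start} overlaps the previous one"
                )
            if (
                self.enforce_min_coasting
                and label == LABEL_COASTING
                and end - start <= MIN_COASTING_S
            ):
                raise ValidationError(
                    f"coasting interval ({start}, {end}) must last more than "
                    f"{MIN_COASTING_S:g} s"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        if not self.intervals:
            return 0.0
        return self.intervals[-1][1]

    def label_at(self, time_s: float) -> str:
        """Label active at an instant, under the half-open convention."""
        for start, end, label in self.intervals:
            if start <= time_s < end:
                return label
        return UNLABELLED


def fine_grain_labels(
    track: LabelTrack, step_s: float, duration_s: float
) -> np.ndarray:
    """Rasterise a label track onto a regular fine time grid.

    Returns an array of ``round(duration_s / step_s)`` label strings, one per
    step start ``i * step_s``. Steps outside every interval get ``unlabelled``.
    A step falling exactly on a boundary takes the later interval (half-open
    convention).
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    n = int(round(duration_s / step_s))
    out = np.full(n, UNLABELLED, dtype=object)
    times = np.arange(n) * step_s
    for start, end, label in track.intervals:
        # half-open [start, end); tolerate float grid jitter at boundaries
        mask = (times >= start - 1e-9) & (times < end - 1e-9)
        out[mask] = label
    return out


def labels_to_track(
    labels: Sequence[str], step_s: float, enforce_min_coasting: bool = True
) -> LabelTrack:
    """Run-length encode a regular label sequence back into a LabelTrack.

    ``unlabelled`` runs become gaps rather than intervals.
    """
    intervals = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] != UNLABELLED:
            intervals.append((i * step_s, j * step_s, labels[i]))
        i = j
    return LabelTrack(intervals, enforce_min_coasting=enforce_min_coasting)
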