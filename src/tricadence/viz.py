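"""Map-style exports: GPS segments coloured by cycling task or annotated
with interval stride counts and rolling cadence.

Outputs are GeoJSON FeatureCollections of LineString features with style
properties — a diff-able, testable artifact that any GIS viewer renders.
The colour legend is fixed: red = out-of-saddle, green = in-saddle,
grey = coasting or unlabelled; cadence maps alternate green/blue interval
segments.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from .cadence import CadenceSeries
from .types import (
    LABEL_COASTING,
    LABEL_IN_SADDLE,
    LABEL_OUT_OF_SADDLE,
    UNLABELLED,
    GpsTrack,
    LabelTrack,
)

__all__ = ["ExportError", "export_task_map", "export_cadence_map", "rolling_average"]

TASK_COLOURS = {
    LABEL_IN_SADDLE: "#1a9850",  # green
    LABEL_OUT_OF_SADDLE: "#d73027",  # red
    LABEL_COASTING: "#888888",  # grey
    UNLABELLED: "#888888",
}
CADENCE_COLOURS = ("#1a9850", "#4575b4")  # alternating green/blue


class ExportError(RuntimeError):
    """Raised when a map export is impossible (e.g. no GPS)."""


def _segment_feature(gps: GpsTrack, start_s, end_s, colour, properties) -> Optional[dict]:
    mask = (gps.t >= start_s) & (gps.t < end_s)
    if np.sum(mask) < 2:
        return None
    coords = np.column_stack([gps.lon[mask], gps.lat[mask]]).tolist()
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "start_s": float(start_s),
            "end_s": float(end_s),
            "duration_s": float(end_s - start_s),
            "stroke": colour,
            **properties,
        },
    }


def _write(features: list, path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def export_task_map(gps: Optional[GpsTrack], track: LabelTrack, path) -> list:
    """Write task-coloured GPS segments; returns the feature list.

    Each labelled interval becomes one LineString of exactly the GPS fixes
    falling in its half-open time span. An empty track yields a single grey
    segment covering the whole GPS span.
    """
    if gps is None or len(gps) == 0:
        raise ExportError("recording has no GPS track to draw on")
    intervals = track.intervals or [
        (float(gps.t[0]), float(gps.t[-1]) + 1e-9, UNLABELLED)
    ]
    features = []
    for start, end, label in intervals:
        feat = _segment_feature(
            gps, start, end, TASK_COLOURS.get(label, "#888888"), {"label": label}
        )
        if feat is not None:
            features.append(feat)
    _write(features, path)
    return features


def rolling_average(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing simple moving average; early entries average what exists."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i in range(len(values)):
        out[i] = values[max(0, i - window + 1) : i + 1].mean()
    return out


def export_cadence_map(
    gps: Optional[GpsTrack],
    cadence: CadenceSeries,
    interval_s: float,
    rolling_window: int,
    path,
) -> list:
    """Write alternating-colour interval segments annotated with event counts
    and a rolling-average cadence.

    ``interval_s`` must be a multiple of the cadence epoch. The rolling
    average is a trailing simple moving average over ``rolling_window``
    epochs, reported at each interval's final epoch.
    """
    if gps is None or len(gps) == 0:
        raise ExportError("recording has no GPS track to draw on")
    ratio = interval_s / cadence.epoch_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"interval_s ({interval_s}) must be a positive multiple of the "
            f"cadence epoch ({cadence.epoch_s})"
        )
    per = int(round(ratio))
    rolling = rolling_average(cadence.cadence_per_min, rolling_window)
    duration = len(cadence.counts) * cadence.epoch_s
    n_intervals = int(np.ceil(duration / interval_s))
    features = []
    for k in range(n_intervals):
        e0, e1 = k * per, min((k + 1) * per, len(cadence.counts))
        feat = _segment_feature(
            gps,
            k * interval_s,
            min((k + 1) * interval_s, duration),
            CADENCE_COLOURS[k % 2],
            {
                "event_count": int(cadence.counts[e0:e1].sum()),
                "rolling_cadence_per_min": float(rolling[e1 - 1]),
            },
        )
        if feat is not None:
            features.append(feat)
    _write(features, path)
    return features
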