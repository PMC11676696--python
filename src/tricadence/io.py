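"""Delimited-text readers and writers for recordings, label tracks and GPS.

The interchange formats are plain CSV (configurable to tab-delimited):

* IMU table: columns ``t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z[,lat,lon]``.
  When GPS is embedded, ``lat``/``lon`` are populated only on the rows whose
  timestamp carries a fix (10 Hz against the 100 Hz inertial grid) and are
  empty elsewhere.
* Label table: columns ``start_s,end_s,label``.
* GPS sub-track: columns ``t,lat,lon``.

Floats are written with 15 significant digits so a write/read round trip is
lossless well past the 1e-9 tolerance the data model promises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CHANNEL_NAMES,
    GpsTrack,
    ImuRecording,
    LabelTrack,
    TableFormatError,
)

__all__ = [
    "TableDialect",
    "read_imu_table",
    "write_imu_table",
    "read_label_track",
    "write_label_track",
    "read_gps_table",
    "write_gps_table",
]

_FLOAT_FMT = "%.15g"


@dataclass(frozen=True)
class TableDialect:
    """Table dialect: delimiter is configurable, '.' decimal and a mandatory
    header row are fixed."""

    delimiter: str = ","


def _read_csv(path, dialect: TableDialect) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=dialect.delimiter)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"cannot parse table {path}: {exc}") from exc


def read_imu_table(
    path, dialect: TableDialect = TableDialect(), sample_rate_hz: float | None = None
) -> ImuRecording:
    """Read a recording from a delimited table and validate it.

    The sample rate is inferred from the median time spacing unless given
    explicitly.
    """
    df = _read_csv(path, dialect)
    required = ("t",) + tuple(CHANNEL_NAMES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"IMU table {path} is missing columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    if sample_rate_hz is None:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        # fall back to the nominal rate on degenerate spacing and let
        # recording validation report the real problem
        sample_rate_hz = 1.0 / dt if dt > 0 else 100.0
    gps = None
    if "lat" in df.columns and "lon" in df.columns:
        fix = df["lat"].notna() & df["lon"].notna()
        if fix.any():
            gps = GpsTrack(
                t=t[fix.to_numpy()],
                lat=df.loc[fix, "lat"].to_numpy(dtype=float),
                lon=df.loc[fix, "lon"].to_numpy(dtype=float),
            )
    channels = {c: df[c].to_numpy(dtype=float) for c in CHANNEL_NAMES}
    return ImuRecording(t=t, sample_rate_hz=sample_rate_hz, gps=gps, **channels)


def write_imu_table(
    rec: ImuRecording, path, dialect: TableDialect = TableDialect()
) -> None:
    """Write a recording as a delimited table; GPS-free recordings get no
    lat/lon columns."""
    data = {"t": rec.t}
    for c in CHANNEL_NAMES:
        data[c] = rec.channel(c)
    df = pd.DataFrame(data)
    if rec.gps is not None and len(rec.gps):
        lat = np.full(len(rec), np.nan)
        lon = np.full(len(rec), np.nan)
        idx = np.searchsorted(rec.t, rec.gps.t)
        idx = np.clip(idx, 0, len(rec) - 1)
        # snap each fix to the nearest inertial sample
        left = np.clip(idx - 1, 0, len(rec) - 1)
        use_left = np.abs(rec.t[left] - rec.gps.t) < np.abs(rec.t[idx] - rec.gps.t)
        idx = np.where(use_left, left, idx)
        lat[idx] = rec.gps.lat
        lon[idx] = rec.gps.lon
        df["lat"] = lat
        df["lon"] = lon
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=_FLOAT_FMT)


def read_label_track(
    path, dialect: TableDialect = TableDialect(), enforce_min_coasting: bool = True
) -> LabelTrack:
    """Read and validate a cycling-task label table."""
    df = _read_csv(path, dialect)
    missing = [c for c in ("start_s", "end_s", "label") if c not in df.columns]
    if missing:
        raise TableFormatError(f"label table {path} is missing columns: {missing}")
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()
    ]
    return LabelTrack(intervals, enforce_min_coasting=enforce_min_coasting)


def write_label_track(
    track: LabelTrack, path, dialect: TableDialect = TableDialect()
) -> None:
    df = pd.DataFrame(track.intervals, columns=["start_s", "end_s", "label"])
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=_FLOAT_FMT)


def read_gps_table(path, dialect: TableDialect = TableDialect()) -> GpsTrack:
    df = _read_csv(path, dialect)
    missing = [c for c in ("t", "lat", "lon") if c not in df.columns]
    if missing:
        raise TableFormatError(f"GPS table {path} is missing columns: {missing}")
    return GpsTrack(
        t=df["t"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        lon=df["lon"].to_numpy(dtype=float),
    )


def write_gps_table(gps: GpsTrack, path, dialect: TableDialect = TableDialect()) -> None:
    df = pd.DataFrame({"t": gps.t, "lat": gps.lat, "lon": gps.lon})
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=_FLOAT_FMT)
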