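"""Data-model invariants and lossless table round trips."""

import numpy as np
import pytest

from tricadence import (
    GpsTrack,
    ImuRecording,
    LabelTrack,
    SyntheticSessionSpec,
    TableFormatError,
    ValidationError,
    fine_grain_labels,
    read_gps_table,
    read_imu_table,
    read_label_track,
    simulate_discipline,
    simulate_gps_track,
    write_gps_table,
    write_imu_table,
    write_label_track,
)
from tricadence.io import TableDialect

from conftest import make_recording


class TestImuRecording:
    def test_minimal_three_row_table(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text(
            "t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z\n"
            "0,0,0,0,0,0,0\n0.01,0,0,0,0,0,0\n0.02,0,0,0,0,0,0\n"
        )
        rec = read_imu_table(path)
        assert len(rec) == 3
        assert rec.sample_rate_hz == pytest.approx(100.0)

    def test_descending_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z\n"
            "0.02,0,0,0,0,0,0\n0.01,0,0,0,0,0,0\n0,0,0,0,0,0,0\n"
        )
        with pytest.raises(ValidationError, match="increasing"):
            read_imu_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("t,acc_x,acc_y\n0,0,0\n")
        with pytest.raises(TableFormatError, match="gyr_x"):
            read_imu_table(path)

    def test_out_of_range_sample_names_row(self):
        acc = np.zeros(100)
        acc[17] = 20.0  # beyond the ±16 g sensor range
        with pytest.raises(ValidationError, match="row 17"):
            make_recording(n=100, acc_z=acc)

    def test_mismatched_channel_lengths_rejected(self):
        with pytest.raises(ValidationError, match="acc_y"):
            ImuRecording(
                t=np.arange(10) / 100.0,
                acc_x=np.zeros(10), acc_y=np.zeros(9), acc_z=np.zeros(10),
                gyr_x=np.zeros(10), gyr_y=np.zeros(10), gyr_z=np.zeros(10),
            )

    def test_gps_outside_time_span_rejected(self):
        gps = GpsTrack(t=[0.0, 30.0], lat=[0.0, 0.0], lon=[0.0, 0.0])
        channels = {c: np.zeros(1000) for c in
                    ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")}
        with pytest.raises(ValidationError, match="GPS"):
            ImuRecording(t=np.arange(1000) / 100.0, gps=gps, **channels)


class TestRoundTrip:
    def test_imu_round_trip_is_identity(self, tmp_path):
        spec = SyntheticSessionSpec("run", 10.0, 170.0, seed=3)
        rec, _ = simulate_discipline(spec)
        rec.gps = simulate_gps_track(9.9, seed=3)
        rec.validate()
        path = tmp_path / "rec.csv"
        write_imu_table(rec, path)
        back = read_imu_table(path)
        np.testing.assert_allclose(back.t, rec.t, atol=1e-9)
        for ch in ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"):
            np.testing.assert_allclose(back.channel(ch), rec.channel(ch), atol=1e-9)
        np.testing.assert_allclose(back.gps.lat, rec.gps.lat, atol=1e-9)
        np.testing.assert_allclose(back.gps.lon, rec.gps.lon, atol=1e-9)

    def test_gps_free_recording_has_no_latlon_columns(self, tmp_path):
        rec = make_recording(n=50)
        path = tmp_path / "nogps.csv"
        write_imu_table(rec, path)
        header = path.read_text().splitlines()[0]
        assert "lat" not in header and "lon" not in header

    def test_single_sample_recording_writes_one_row(self, tmp_path):
        rec = make_recording(n=1)
        path = tmp_path / "one.csv"
        write_imu_table(rec, path)
        assert len(path.read_text().strip().splitlines()) == 2  # header + 1 row

    def test_tab_dialect_round_trip(self, tmp_path):
        rec = make_recording(n=20)
        path = tmp_path / "rec.tsv"
        dialect = TableDialect(delimiter="\t")
        write_imu_table(rec, path, dialect)
        back = read_imu_table(path, dialect)
        np.testing.assert_allclose(back.acc_z, rec.acc_z, atol=1e-9)

    def test_label_track_round_trip_bitwise(self, tmp_path):
        track = LabelTrack([(0.0, 20.0, "in_saddle"), (20.0, 40.0, "out_of_saddle"),
                            (45.0, 50.0, "coasting")])
        path = tmp_path / "labels.csv"
        write_label_track(track, path)
        assert read_label_track(path).intervals == track.intervals

    def test_gps_table_round_trip(self, tmp_path):
        gps = simulate_gps_track(30.0, jitter_m=1.0, seed=4)
        path = tmp_path / "gps.csv"
        write_gps_table(gps, path)
        back = read_gps_table(path)
        np.testing.assert_allclose(back.lat, gps.lat, atol=1e-9)


class TestLabelTrack:
    def test_two_interval_track_valid(self):
        track = LabelTrack([(0, 20, "in_saddle"), (20, 40, "out_of_saddle")])
        assert len(track) == 2

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            LabelTrack([(0, 20, "in_saddle"), (10, 30, "coasting")])

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text("start_s,end_s,label\n0,10,sprinting\n")
        with pytest.raises(TableFormatError, match="sprinting"):
            read_label_track(path)

    def test_sub_second_coasting_rejected(self):
        # coasting means not pedalling for MORE than one second
        with pytest.raises(ValidationError, match="coasting"):
            LabelTrack([(0.0, 0.5, "coasting")])

    def test_label_at_uses_half_open_intervals(self):
        track = LabelTrack([(0, 1, "in_saddle"), (1, 2, "out_of_saddle")])
        assert track.label_at(1.0) == "out_of_saddle"
        assert track.label_at(2.0) == "unlabelled"


class TestFineGrainLabels:
    def test_full_coverage(self):
        track = LabelTrack([(0, 1, "in_saddle")])
        fine = fine_grain_labels(track, 0.1, 1.0)
        assert list(fine) == ["in_saddle"] * 10

    def test_empty_track_is_unlabelled(self):
        fine = fine_grain_labels(LabelTrack([]), 0.1, 1.0)
        assert list(fine) == ["unlabelled"] * 10

    def test_boundary_step_takes_later_interval(self):
        track = LabelTrack(
            [(0, 0.5, "in_saddle"), (0.5, 1, "coasting")],
            enforce_min_coasting=False,
        )
        fine = fine_grain_labels(track, 0.1, 1.0)
        # enumerate the half-open convention: steps 0..4 early, 5..9 late
        assert list(fine) == ["in_saddle"] * 5 + ["coasting"] * 5

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            fine_grain_labels(LabelTrack([]), 0.1, -1.0)

    @pytest.mark.parametrize("step,duration", [(0.1, 1.0), (0.25, 2.0), (0.1, 0.35),
                                               (0.5, 10.0), (0.3, 1.0)])
    def test_length_is_rounded_ratio(self, step, duration):
        fine = fine_grain_labels(LabelTrack([]), step, duration)
        assert len(fine) == round(duration / step)
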