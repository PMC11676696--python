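"""Event detection, cadence epoching, sync taps and count metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricadence import (
    CadenceSeries,
    DisciplineProfile,
    EventSeries,
    SyncDetectionError,
    cadence_rmse,
    cadence_series,
    count_accuracy,
    default_profiles,
    detect_events,
    detect_sync_taps,
    inject_sync_taps,
    relative_error,
)

from conftest import make_recording


def sinusoid_recording(freq_hz, duration_s=60.0, channel="acc_z", amplitude=1.0):
    fs = 100.0
    t = np.arange(int(duration_s * fs)) / fs
    return make_recording(
        n=len(t), **{channel: amplitude * np.sin(2 * np.pi * freq_hz * t)}
    )


class TestDetectEvents:
    def test_zero_signal_yields_no_events(self):
        rec = make_recording(n=6000, acc_z=np.zeros(6000))
        ev = detect_events(rec, default_profiles()["run"])
        assert len(ev) == 0

    def test_swim_sinusoid_counts_peaks_and_troughs(self):
        # 1 Hz roll for 60 s: 60 peaks + 60 troughs
        rec = sinusoid_recording(1.0, channel="acc_y")
        ev = detect_events(rec, default_profiles()["swim"])
        assert abs(len(ev) - 120) <= 1

    def test_run_sinusoid_counts_peaks_only(self):
        rec = sinusoid_recording(2.8)
        ev = detect_events(rec, default_profiles()["run"])
        assert abs(len(ev) - 168) <= 1

    @pytest.mark.parametrize("duration_s", [10.0, 60.0, 600.0])
    def test_analytic_extremum_count_oracle(self, duration_s):
        # closed form: a 2.5 Hz sinusoid has floor-or-so 2.5*duration peaks
        rec = sinusoid_recording(2.5, duration_s=duration_s)
        ev = detect_events(rec, default_profiles()["cycle"])
        assert abs(len(ev) - int(2.5 * duration_s)) <= 1

    def test_too_short_recording_rejected(self):
        rec = make_recording(n=40)
        with pytest.raises(ValueError, match="too short"):
            detect_events(rec, default_profiles()["run"])

    def test_min_interval_never_violated_on_noise(self, rng):
        rec = make_recording(n=12_000, acc_z=rng.normal(0, 0.5, 12_000))
        profile = default_profiles()["cycle"]
        ev = detect_events(rec, profile)
        if len(ev) > 1:
            assert np.min(np.diff(ev.event_times_s)) >= profile.min_interval_s - 1.5 / 100.0

    def test_conflicting_candidates_are_suppressed_greedily(self):
        # peaks and troughs of a 1 Hz sinusoid alternate every 0.5 s; with a
        # 0.6 s minimum interval adjacent extrema conflict, so the survivors
        # must respect the spacing floor and their count is bounded by the
        # packing limits (60 s / 1.2 s .. 60 s / 0.6 s)
        rec = sinusoid_recording(1.0, channel="acc_y")
        profile = DisciplineProfile(
            "swim", (0.5, 1.4), 0.6, channel="acc_y", polarity="peaks_and_troughs"
        )
        ev = detect_events(rec, profile)
        assert 50 <= len(ev) <= 61
        assert np.min(np.diff(ev.event_times_s)) >= 0.6 - 1.5 / 100.0


class TestCadenceSeries:
    def test_uniform_events_give_constant_cadence(self):
        ev = EventSeries(np.arange(120) * 0.5)  # 120 events over 60 s
        series = cadence_series(ev, 10.0, 60.0)
        assert list(series.counts) == [20] * 6
        assert np.allclose(series.cadence_per_min, 120.0)

    def test_empty_series_all_zero(self):
        series = cadence_series(EventSeries(np.empty(0)), 10.0, 60.0)
        assert series.total == 0 and len(series.counts) == 6

    def test_half_open_epoch_binning(self):
        series = cadence_series(EventSeries([0.0, 10.0]), 10.0, 20.0)
        assert list(series.counts) == [1, 1]

    def test_epoch_count_is_ceiling(self):
        assert len(cadence_series(EventSeries(np.empty(0)), 10.0, 61.0).counts) == 7

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        times=st.lists(st.floats(0.0, 99.0), min_size=0, max_size=60, unique=True),
        epoch=st.floats(1.0, 30.0),
    )
    def test_conservation_property(self, times, epoch):
        ev = EventSeries(np.sort(np.asarray(times)))
        series = cadence_series(ev, epoch, 100.0)
        n_cover = len(series.counts) * epoch
        assert series.total == np.sum(ev.event_times_s < n_cover)


class TestSyncTaps:
    def test_five_taps_anchor_on_last(self):
        rec = make_recording(n=800)
        inject_sync_taps(rec, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert detect_sync_taps(rec) == pytest.approx(5.0, abs=0.02)

    def test_quiet_recording_reports_zero(self):
        rec = make_recording(n=800, acc_x=np.zeros(800))
        with pytest.raises(SyncDetectionError) as err:
            detect_sync_taps(rec)
        assert err.value.found == 0

    def test_three_taps_reports_three(self):
        rec = make_recording(n=800)
        inject_sync_taps(rec, [1.0, 2.0, 3.0])
        with pytest.raises(SyncDetectionError) as err:
            detect_sync_taps(rec, n_taps=5)
        assert err.value.found == 3


class TestCountMetrics:
    @pytest.mark.parametrize(
        "detected,truth,expected",
        [(341, 341, 100.0), (338, 341, pytest.approx(99.12, abs=0.01)),
         (0, 341, 0.0), (682, 341, 0.0)],
    )
    def test_count_accuracy(self, detected, truth, expected):
        assert count_accuracy(detected, truth) == expected

    def test_count_accuracy_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            count_accuracy(10, 0)

    def test_rmse_identical_is_zero(self):
        a = cadence_series(EventSeries(np.arange(10.0)), 5.0, 30.0)
        assert cadence_rmse(a, a) == 0.0

    def test_rmse_constant_offset(self):
        starts = np.arange(3) * 60.0
        det = CadenceSeries(starts, [80, 80, 80], 60.0)
        tru = CadenceSeries(starts, [78, 78, 78], 60.0)
        assert cadence_rmse(det, tru) == pytest.approx(2.0)

    def test_rmse_hand_computed(self):
        starts = np.arange(3) * 60.0
        det = CadenceSeries(starts, [83, 76, 80], 60.0)
        tru = CadenceSeries(starts, [80, 80, 80], 60.0)
        assert cadence_rmse(det, tru) == pytest.approx(np.sqrt(25.0 / 3.0), abs=1e-9)

    def test_rmse_mismatched_grids_rejected(self):
        a = CadenceSeries([0.0], [5], 60.0)
        b = CadenceSeries([0.0], [5], 30.0)
        with pytest.raises(ValueError, match="grid"):
            cadence_rmse(a, b)

    @pytest.mark.parametrize(
        "detected,truth,expected",
        [(1000, 1000, 0.0), (1030, 1000, 3.0), (970, 1000, 3.0)],
    )
    def test_relative_error(self, detected, truth, expected):
        assert relative_error(detected, truth) == pytest.approx(expected)

    def test_relative_error_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error(10, 0)
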