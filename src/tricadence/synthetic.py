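"""Seeded synthetic trunk-IMU sessions with exact ground truth.

The generator emulates the cyclic locomotion signals a trunk-mounted sensor
records in each triathlon discipline: the selected primary channel carries a
fundamental at the cadence frequency plus harmonics, a gravity baseline, and
seeded Gaussian noise. For running and cycling the fundamental sits at
``cadence / 60`` Hz on the vertical accelerometer (one impact or one pedal
stroke per cycle, counted at signal peaks). For swimming the trunk rolls at
half the stroke rate, so the mediolateral channel oscillates at
``cadence / 120`` Hz and strokes are counted at both peaks and troughs.

Ground-truth event times are the analytic extremum times of the noise-free
waveform, so event counts are exact integers derived from the session
specification — no detection is involved.

Scheduled cycling sessions additionally switch between per-block signal
regimes: seated pedalling (moderate vertical oscillation at the pedal
frequency), out-of-saddle pedalling (double-amplitude vertical oscillation,
a vertical baseline shift, and a strong low-frequency mediolateral rocking
component at half the pedal frequency with an in-band second harmonic), and
coasting (road noise only, no pedal oscillation). The label track mirrors
the schedule exactly. Two schedule builders reproduce the two data-collection
styles of interest: race-style sessions dominated by seated riding with
short standing efforts, and balanced sessions of equal 20 s task blocks.

Default cadences follow observed triathlon means (swim ≈ 79 strokes/min,
cycle ≈ 157.5 pedal strokes/min, run ≈ 172 strides/min). Amplitudes are
order-of-magnitude choices (0.1–1.5 g) for trunk acceleration; they are not
measured values and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .cadence import CadenceSeries, EventSeries, cadence_series
from .types import (
    LABEL_COASTING,
    LABEL_IN_SADDLE,
    LABEL_OUT_OF_SADDLE,
    GpsTrack,
    ImuRecording,
    LabelTrack,
)

__all__ = [
    "SyntheticSessionSpec",
    "GroundTruth",
    "simulate_discipline",
    "simulate_cycling_session",
    "simulate_gps_track",
    "balanced_schedule",
    "race_schedule",
    "inject_sync_taps",
]

#: Per-discipline generator defaults: primary channel, peak amplitude (g),
#: gyro oscillation amplitude (deg/s), nominal cadence (events/min).
DISCIPLINE_DEFAULTS = {
    "swim": {"channel": "acc_y", "amplitude_g": 0.35, "gyr_amp_dps": 30.0, "cadence": 79.0},
    "cycle": {"channel": "acc_z", "amplitude_g": 0.30, "gyr_amp_dps": 15.0, "cadence": 157.5},
    "run": {"channel": "acc_z", "amplitude_g": 0.80, "gyr_amp_dps": 25.0, "cadence": 172.0},
}

DEFAULT_HARMONICS = (1.0, 0.3, 0.1)

# scheduled-cycling regime parameters (g unless noted)
PEDAL_AMP_IN = 0.30
PEDAL_AMP_OUT = 0.60
ROCK_AMP_OUT = 0.60
ROCK_HARMONICS = (1.0, 0.5)
BASELINE_SHIFT_OUT = 0.15


@dataclass
class SyntheticSessionSpec:
    """Specification of one synthetic session.

    ``cadence_per_min`` is either a constant or a piecewise-constant profile
    given as ``[(segment_duration_s, cadence), ...]`` summing to the session
    duration. ``task_schedule`` (cycling only) is an ordered list of
    ``(duration_s, label)`` blocks that must sum to ``duration_s``.
    """

    discipline: str
    duration_s: float
    cadence_per_min: Union[float, Sequence[Tuple[float, float]], None] = None
    amplitude_g: Optional[float] = None
    harmonic_weights: Tuple[float, ...] = DEFAULT_HARMONICS
    noise_sd_g: float = 0.08
    noise_sd_dps: float = 5.0
    baseline_g: dict = field(default_factory=lambda: {"acc_z": 1.0})
    channel: Optional[str] = None
    task_schedule: Optional[Sequence[Tuple[float, str]]] = None
    sample_rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discipline not in DISCIPLINE_DEFAULTS:
            raise ValueError(f"unknown discipline {self.discipline!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_g < 0 or self.noise_sd_dps < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.cadence_per_min is None:
            self.cadence_per_min = DISCIPLINE_DEFAULTS[self.discipline]["cadence"]
        if np.isscalar(self.cadence_per_min):
            if self.cadence_per_min <= 0:
                raise ValueError("cadence_per_min must be positive")
        else:
            segs = [(float(d), float(c)) for d, c in self.cadence_per_min]
            if any(d <= 0 or c <= 0 for d, c in segs):
                raise ValueError("cadence segments need positive duration and cadence")
            if abs(sum(d for d, _ in segs) - self.duration_s) > 1e-6:
                raise ValueError("cadence segment durations must sum to duration_s")
            self.cadence_per_min = segs
        if self.task_schedule is not None:
            sched = [(float(d), str(lab)) for d, lab in self.task_schedule]
            if any(d <= 0 for d, _ in sched):
                raise ValueError("schedule blocks need positive duration")
            if abs(sum(d for d, _ in sched) - self.duration_s) > 1e-6:
                raise ValueError("task_schedule durations must sum to duration_s")
            self.task_schedule = sched

    @property
    def primary_channel(self) -> str:
        return self.channel or DISCIPLINE_DEFAULTS[self.discipline]["channel"]

    @property
    def primary_amplitude(self) -> float:
        if self.amplitude_g is not None:
            return self.amplitude_g
        return DISCIPLINE_DEFAULTS[self.discipline]["amplitude_g"]

    def cadence_segments(self) -> list:
        if np.isscalar(self.cadence_per_min):
            return [(self.duration_s, float(self.cadence_per_min))]
        return list(self.cadence_per_min)


@dataclass
class GroundTruth:
    """Exact per-session truth: event times, labels, and cadence helpers."""

    event_times_s: np.ndarray
    label_track: Optional[LabelTrack] = None

    @property
    def event_count(self) -> int:
        return len(self.event_times_s)

    def event_series(self, discipline: str = "") -> EventSeries:
        return EventSeries(self.event_times_s, discipline=discipline)

    def true_cadence_series(self, epoch_s: float, duration_s: float) -> CadenceSeries:
        return cadence_series(self.event_series(), epoch_s, duration_s)


def _waveform(weights: Sequence[float], phase: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phase)
    for h, w in enumerate(weights, start=1):
        out += w * np.sin(h * phase)
    return out


def _extremum_phases(weights: Sequence[float]) -> Tuple[float, float]:
    """Peak and trough phase of one period of the harmonic template."""
    theta = np.linspace(0.0, 2 * np.pi, 200001)
    g = _waveform(weights, theta)
    return float(theta[np.argmax(g)]), float(theta[np.argmin(g)])


def _segment_events(
    f: float, t0: float, t1: float, phase0: float, weights, troughs: bool
) -> np.ndarray:
    """Analytic extremum times of the clean waveform in [t0, t1)."""
    peak_phase, trough_phase = _extremum_phases(weights)
    targets = [peak_phase] + ([trough_phase] if troughs else [])
    times = []
    for target in targets:
        # phase(t) = phase0 + 2*pi*f*(t - t0) == target (mod 2*pi)
        first = t0 + ((target - phase0) % (2 * np.pi)) / (2 * np.pi * f)
        k = np.arange(int(np.ceil((t1 - first) * f)) + 1)
        tt = first + k / f
        times.append(tt[(tt >= t0) & (tt < t1 - 1e-12)])
    return np.sort(np.concatenate(times))


def simulate_discipline(spec: SyntheticSessionSpec) -> Tuple[ImuRecording, GroundTruth]:
    """Generate one single-discipline session (no task schedule).

    The primary channel carries the harmonic waveform at the fundamental
    frequency (``cadence/60`` Hz, or ``cadence/120`` for the swim roll
    channel), secondary channels carry an attenuated phase-shifted copy, the
    gyroscope channels oscillate at the same frequency, and every channel
    gets independent seeded Gaussian noise. Identical specs and seeds yield
    bit-identical output.
    """
    if spec.task_schedule is not None:
        raise ValueError("use simulate_cycling_session for scheduled sessions")
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    swim = spec.discipline == "swim"
    cycles_per_event = 1.0 / 2.0 if swim else 1.0  # swim: two events per roll cycle

    # piecewise-constant fundamental frequency, continuous phase
    phase = np.zeros(n)
    events = []
    acc_phase = 0.0
    seg_t0 = 0.0
    for seg_dur, cad in spec.cadence_segments():
        f = cad / 60.0 * cycles_per_event
        seg_t1 = seg_t0 + seg_dur
        m = (t >= seg_t0 - 1e-12) & (t < seg_t1 - 1e-12)
        phase[m] = acc_phase + 2 * np.pi * f * (t[m] - seg_t0)
        events.append(
            _segment_events(f, seg_t0, seg_t1, acc_phase, spec.harmonic_weights, swim)
        )
        acc_phase += 2 * np.pi * f * seg_dur
        seg_t0 = seg_t1
    event_times = np.concatenate(events)

    primary = spec.primary_channel
    amp = spec.primary_amplitude
    carrier = _waveform(spec.harmonic_weights, phase)
    channels = {}
    for name in ("acc_x", "acc_y", "acc_z"):
        base = spec.baseline_g.get(name, 0.0)
        if name == primary:
            sig = amp * carrier
        else:
            sig = 0.25 * amp * _waveform(spec.harmonic_weights, phase + np.pi / 3)
        channels[name] = base + sig + rng.normal(0.0, spec.noise_sd_g, n)
    gyr_amp = DISCIPLINE_DEFAULTS[spec.discipline]["gyr_amp_dps"]
    for i, name in enumerate(("gyr_x", "gyr_y", "gyr_z")):
        sig = gyr_amp * np.sin(phase + i * np.pi / 4)
        channels[name] = sig + rng.normal(0.0, spec.noise_sd_dps, n)

    rec = ImuRecording(
        t=t,
        sample_rate_hz=fs,
        meta={"discipline": spec.discipline, "seed": spec.seed, "synthetic": True},
        **channels,
    )
    return rec, GroundTruth(event_times_s=event_times)


def simulate_cycling_session(spec: SyntheticSessionSpec) -> Tuple[ImuRecording, GroundTruth]:
    """Generate a scheduled cycling session with per-block signal regimes.

    Ground-truth pedal events exist only in pedalling blocks; coasting
    blocks carry road noise alone. The returned label track has one interval
    per schedule block.
    """
    if spec.discipline != "cycle":
        raise ValueError("scheduled sessions are cycling-specific")
    if spec.task_schedule is None:
        raise ValueError("spec.task_schedule is required")
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    cad = spec.cadence_per_min
    if not np.isscalar(cad):
        raise ValueError("scheduled sessions use a constant cadence")
    f_pedal = float(cad) / 60.0
    f_rock = f_pedal / 2.0

    acc_z = np.full(n, spec.baseline_g.get("acc_z", 1.0))
    acc_y = np.zeros(n)
    acc_x = np.full(n, spec.baseline_g.get("acc_x", 0.0))
    gyr_x = np.zeros(n)
    gyr_z = np.zeros(n)

    intervals = []
    events = []
    block_t0 = 0.0
    for dur, label in spec.task_schedule:
        block_t1 = block_t0 + dur
        m = (t >= block_t0 - 1e-12) & (t < block_t1 - 1e-12)
        trel = t[m] - block_t0
        if label in (LABEL_IN_SADDLE, LABEL_OUT_OF_SADDLE):
            pedal_amp = PEDAL_AMP_IN if label == LABEL_IN_SADDLE else PEDAL_AMP_OUT
            acc_z[m] += pedal_amp * np.sin(2 * np.pi * f_pedal * trel)
            gyr_z[m] += 10.0 * np.sin(2 * np.pi * f_pedal * trel)
            events.append(
                _segment_events(f_pedal, block_t0, block_t1, 0.0, (1.0,), False)
            )
            if label == LABEL_OUT_OF_SADDLE:
                acc_z[m] += BASELINE_SHIFT_OUT
                acc_y[m] += ROCK_AMP_OUT * _waveform(
                    ROCK_HARMONICS, 2 * np.pi * f_rock * trel
                )
                gyr_x[m] += 40.0 * np.sin(2 * np.pi * f_rock * trel)
            else:
                acc_y[m] += 0.05 * np.sin(2 * np.pi * f_pedal * trel)
        elif label != LABEL_COASTING:
            raise ValueError(f"unknown schedule label {label!r}")
        intervals.append((block_t0, block_t1, label))
        block_t0 = block_t1

    channels = {
        "acc_x": acc_x + rng.normal(0.0, spec.noise_sd_g, n),
        "acc_y": acc_y + rng.normal(0.0, spec.noise_sd_g, n),
        "acc_z": acc_z + rng.normal(0.0, spec.noise_sd_g, n),
        "gyr_x": gyr_x + rng.normal(0.0, spec.noise_sd_dps, n),
        "gyr_y": rng.normal(0.0, spec.noise_sd_dps, n),
        "gyr_z": gyr_z + rng.normal(0.0, spec.noise_sd_dps, n),
    }
    rec = ImuRecording(
        t=t,
        sample_rate_hz=fs,
        meta={"discipline": "cycle", "seed": spec.seed, "synthetic": True},
        **channels,
    )
    truth = GroundTruth(
        event_times_s=np.sort(np.concatenate(events)) if events else np.empty(0),
        label_track=LabelTrack(intervals),
    )
    return rec, truth


def balanced_schedule(
    n_repeats: int,
    block_s: float = 20.0,
    labels: Sequence[str] = (LABEL_IN_SADDLE, LABEL_OUT_OF_SADDLE, LABEL_COASTING),
) -> list:
    """Equal-duration task blocks cycled ``n_repeats`` times (the controlled
    second-round collection style)."""
    return [(block_s, lab) for _ in range(n_repeats) for lab in labels]


def race_schedule(
    duration_s: float,
    seed: int = 0,
    effort_s: Tuple[float, float] = (2.0, 4.0),
    in_saddle_s: Tuple[float, float] = (40.0, 90.0),
    coast_s: Tuple[float, float] = (2.0, 6.0),
    coast_every: int = 3,
    quantum: Optional[float] = None,
) -> list:
    """Race-style schedule: long seated stretches with short standing efforts
    and occasional coasting, leaving seated riding heavily overrepresented
    (~90% of the duration at the defaults).

    ``quantum`` rounds every block duration to a multiple (e.g. 2.5 s to
    align blocks with the STFT window grid).
    """
    rng = np.random.default_rng(seed)

    def _draw(lo_hi) -> float:
        d = rng.uniform(*lo_hi)
        if quantum:
            d = max(quantum, round(d / quantum) * quantum)
        return d

    sched = []
    elapsed = 0.0
    k = 0
    while True:
        for dur, lab in (
            (_draw(in_saddle_s), LABEL_IN_SADDLE),
            (_draw(effort_s), LABEL_OUT_OF_SADDLE),
        ):
            if elapsed + dur > duration_s:
                break
            sched.append((dur, lab))
            elapsed += dur
        else:
            k += 1
            if k % coast_every == 0:
                dur = _draw(coast_s)
                if elapsed + dur <= duration_s and dur > 1.0:
                    sched.append((dur, LABEL_COASTING))
                    elapsed += dur
            continue
        break
    if duration_s - elapsed > 1e-9:
        sched.append((duration_s - elapsed, LABEL_IN_SADDLE))
    return sched


def simulate_gps_track(
    duration_s: float,
    course: str = "rectangle",
    perimeter_m: float = 5000.0,
    speed_mps: float = 8.33,
    jitter_m: float = 0.0,
    seed: int = 0,
    origin: Tuple[float, float] = (-32.0, 115.85),
    rate_hz: float = 10.0,
) -> GpsTrack:
    """A 10 Hz lat/lon track along an idealised course.

    ``rectangle`` follows a closed 2:1 rectangle of the given perimeter
    (emulating an elongated closed cycling circuit); ``out_and_back``
    shuttles along a straight line of half the total distance. Positions get
    isotropic Gaussian jitter of SD ``jitter_m``.
    """
    if duration_s <= 0 or speed_mps <= 0:
        raise ValueError("duration and speed must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    s = speed_mps * t
    if course == "rectangle":
        w = perimeter_m / 6.0  # 2:1 aspect: L = 2w, perimeter = 6w
        length = 2.0 * w
        d = np.mod(s, perimeter_m)
        x = np.empty_like(d)
        y = np.empty_like(d)
        leg1 = d < length
        leg2 = (d >= length) & (d < length + w)
        leg3 = (d >= length + w) & (d < 2 * length + w)
        leg4 = d >= 2 * length + w
        x[leg1], y[leg1] = d[leg1], 0.0
        x[leg2], y[leg2] = length, d[leg2] - length
        x[leg3], y[leg3] = length - (d[leg3] - length - w), w
        x[leg4], y[leg4] = 0.0, w - (d[leg4] - 2 * length - w)
    elif course == "out_and_back":
        half = speed_mps * duration_s / 2.0
        d = np.mod(s, 2 * half)
        x = np.where(d < half, d, 2 * half - d)
        y = np.zeros_like(x)
    else:
        raise ValueError(f"unknown course {course!r}")
    if jitter_m > 0:
        x = x + rng.normal(0.0, jitter_m, len(x))
        y = y + rng.normal(0.0, jitter_m, len(y))
    lat0, lon0 = origin
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.deg2rad(lat0))
    return GpsTrack(t=t, lat=lat0 + y / m_per_deg_lat, lon=lon0 + x / m_per_deg_lon)


def inject_sync_taps(
    rec: ImuRecording,
    tap_times_s: Sequence[float],
    amplitude_g: float = 8.0,
    width_s: float = 0.06,
) -> ImuRecording:
    """Superimpose the video-sync signature — short forward-axis spikes — at
    the given times (in place), clipping to the sensor range."""
    fs = rec.sample_rate_hz
    half = max(int(round(width_s * fs / 2)), 1)
    pulse = amplitude_g * np.sin(np.linspace(0, np.pi, 2 * half + 1))
    for tap in tap_times_s:
        i = int(round(tap * fs))
        lo, hi = max(i - half, 0), min(i + half + 1, len(rec))
        rec.acc_x[lo:hi] += pulse[lo - (i - half) : len(pulse) - ((i + half + 1) - hi)]
    np.clip(rec.acc_x, -16.0, 16.0, out=rec.acc_x)
    return rec
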