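"""Band-pass filtering shared by the peak counter and the feature extractor.

The filter is a sixth-order Butterworth band-pass (2–3 Hz for cycling and
running, 0.5–1.4 Hz for swimming), chosen for its maximally flat passband.
"Sixth order" refers to the order of the band-pass transfer function itself,
so the underlying low-pass prototype has order three.

Filtering is applied forward–backward (zero phase) so that detected event
times stay aligned with externally synchronised video: cadence analysis is
offline, so causality is not needed. Note that the forward–backward pass
squares the magnitude response, sharpening the effective roll-off beyond a
single sixth-order pass. Reflective padding suppresses start-up transients
at segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["BandpassSpec", "design_bandpass", "apply_zero_phase", "frequency_response"]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass specification.

    ``order`` is the order of the band-pass filter (must be even; the
    low-pass prototype has order ``order // 2``).
    """

    low_hz: float
    high_hz: float
    sample_rate_hz: float = 100.0
    order: int = 6

    def __post_init__(self) -> None:
        nyq = self.sample_rate_hz / 2.0
        if not (0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"cutoffs must satisfy 0 < low ({self.low_hz}) < high "
                f"({self.high_hz}) < Nyquist ({nyq})"
            )
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be an even integer >= 2")


def design_bandpass(spec: BandpassSpec) -> np.ndarray:
    """Design the filter, returned as second-order sections (stable form)."""
    return signal.butter(
        spec.order // 2,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=spec.sample_rate_hz,
        output="sos",
    )


def frequency_response(spec: BandpassSpec, freqs_hz) -> np.ndarray:
    """Single-pass magnitude response |H(f)| at the requested frequencies."""
    sos = design_bandpass(spec)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=spec.sample_rate_hz)
    return np.abs(h)


def apply_zero_phase(x, spec: BandpassSpec) -> np.ndarray:
    """Filter a 1-D signal forward–backward (zero phase lag).

    The output has the same length as the input. The signal must be longer
    than three times the filter order.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"signal of length {len(x)} is too short for zero-phase filtering "
            f"(need > {3 * spec.order} samples)"
        )
    sos = design_bandpass(spec)
    # reflective padding, ~3 periods of the lowest passband frequency
    padlen = min(len(x) - 1, int(round(3 * spec.sample_rate_hz / spec.low_hz)))
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
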