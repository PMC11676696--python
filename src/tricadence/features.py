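"""Windowed spectral features for cycling-task recognition.

The six inertial channels are combined, band-pass filtered with the same
2–3 Hz filter used for cycling peak counting (configurable, and switchable
off for experimentation), and converted to the frequency domain with a
short-time Fourier transform: rectangular windows of 250 samples (2.5 s at
100 Hz) with no overlap. Each window then contributes a one-sided magnitude
spectrum of ``window/2 + 1`` bins per channel — 126 bins per channel, 756
features per window at the defaults.

Features are z-scored with a standard scaler fitted on training windows
only. Task labels, kept on a fine 0.1 s grid, are assigned to windows by
majority vote among the fine steps each window covers; ``unlabelled`` steps
do not vote, and ties break towards the label occurring earliest within the
window (deterministic, independent of label dictionary order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import BandpassSpec, apply_zero_phase
from .types import CHANNEL_NAMES, ImuRecording, UNLABELLED

__all__ = [
    "StftConfig",
    "FeatureMatrix",
    "Standardizer",
    "stft_magnitudes",
    "fit_standardizer",
    "apply_standardizer",
    "align_labels",
]


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform configuration.

    ``prefilter_band`` applies the cycling band-pass to every channel before
    the transform; set it to ``None`` to keep the full spectrum.
    """

    window_samples: int = 250
    overlap_samples: int = 0
    sample_rate_hz: float = 100.0
    prefilter_band: Optional[tuple] = (2.0, 3.0)
    prefilter_order: int = 6

    def __post_init__(self) -> None:
        if self.window_samples <= 0:
            raise ValueError("window_samples must be positive")
        if not (0 <= self.overlap_samples < self.window_samples):
            raise ValueError("overlap must satisfy 0 <= overlap < window")

    @property
    def hop_samples(self) -> int:
        return self.window_samples - self.overlap_samples

    @property
    def window_s(self) -> float:
        return self.window_samples / self.sample_rate_hz

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.sample_rate_hz

    @property
    def bins_per_channel(self) -> int:
        return self.window_samples // 2 + 1

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.window_samples:
            return 0
        return (n_samples - self.window_samples) // self.hop_samples + 1


@dataclass
class FeatureMatrix:
    """Per-window spectral magnitudes, one row per window.

    Columns are ordered channel-major: all bins of ``acc_x``, then ``acc_y``,
    and so on in canonical channel order.
    """

    window_starts_s: np.ndarray
    values: np.ndarray  # (n_windows, n_channels * n_bins)
    channels: tuple = CHANNEL_NAMES
    freqs_hz: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_names(self) -> list:
        n_bins = self.n_features // len(self.channels)
        return [f"{ch}_bin{b}" for ch in self.channels for b in range(n_bins)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names())
        df.insert(0, "window_start_s", self.window_starts_s)
        return df


def stft_magnitudes(rec: ImuRecording, cfg: StftConfig = StftConfig()) -> FeatureMatrix:
    """One-sided STFT magnitude spectra of all six channels, per window.

    Windows are rectangular (no taper), which keeps the bin count and the
    no-overlap arithmetic exact. Raises if the recording is shorter than one
    window.
    """
    n = len(rec)
    if n < cfg.window_samples:
        raise ValueError(
            f"recording of {n} samples is shorter than one window "
            f"({cfg.window_samples} samples)"
        )
    n_win = cfg.n_windows(n)
    starts = np.arange(n_win) * cfg.hop_samples
    blocks = []
    for ch in CHANNEL_NAMES:
        x = rec.channel(ch)
        if cfg.prefilter_band is not None:
            low, high = cfg.prefilter_band
            spec = BandpassSpec(
                low_hz=low,
                high_hz=high,
                sample_rate_hz=rec.sample_rate_hz,
                order=cfg.prefilter_order,
            )
            x = apply_zero_phase(x, spec)
        frames = np.stack([x[s : s + cfg.window_samples] for s in starts])
        blocks.append(np.abs(np.fft.rfft(frames, axis=1)))
    values = np.concatenate(blocks, axis=1)
    freqs = np.fft.rfftfreq(cfg.window_samples, d=1.0 / rec.sample_rate_hz)
    return FeatureMatrix(
        window_starts_s=starts / rec.sample_rate_hz,
        values=values,
        channels=CHANNEL_NAMES,
        freqs_hz=freqs,
    )


@dataclass
class Standardizer:
    """Per-feature z-scoring state (mean and SD from training windows only).

    Features with zero training SD map to zero after standardisation, which
    keeps constant (e.g. silent-channel) features from blowing up.
    """

    mean_: np.ndarray
    sd_: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.mean_.shape[0]:
            raise ValueError(
                f"feature dimension {values.shape[-1]} does not match the "
                f"fitted standardizer ({self.mean_.shape[0]})"
            )
        out = values - self.mean_
        nonzero = self.sd_ > 0
        out[..., nonzero] /= self.sd_[nonzero]
        out[..., ~nonzero] = 0.0
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"], dtype=float), np.asarray(d["sd"], dtype=float))


def _values_of(features) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)


def fit_standardizer(training) -> Standardizer:
    """Fit per-feature mean/SD on a training feature matrix (>= 2 windows)."""
    values = _values_of(training)
    if values.shape[0] < 2:
        raise ValueError("need at least two training windows to fit a standardizer")
    return Standardizer(mean_=values.mean(axis=0), sd_=values.std(axis=0))


def apply_standardizer(state: Standardizer, features):
    """Z-score a feature matrix with a previously fitted standardizer."""
    values = state.transform(_values_of(features))
    if isinstance(features, FeatureMatrix):
        return FeatureMatrix(
            window_starts_s=features.window_starts_s,
            values=values,
            channels=features.channels,
            freqs_hz=features.freqs_hz,
        )
    return values


def align_labels(
    fine: Sequence[str],
    cfg: StftConfig = StftConfig(),
    step_s: float = 0.1,
    n_windows: Optional[int] = None,
) -> np.ndarray:
    """Assign each STFT window the modal label of the fine steps it covers.

    ``fine`` is a label sequence on a regular ``step_s`` grid (0.1 s by
    default). ``unlabelled`` steps are excluded from the vote; a window whose
    steps are all unlabelled stays ``unlabelled``. Ties break towards the
    label that first occurs within the window.
    """
    fine = list(fine)
    if not fine:
        raise ValueError("fine label sequence is empty")
    duration = len(fine) * step_s
    n_fit = cfg.n_windows(int(round(duration * cfg.sample_rate_hz)))
    if n_windows is None:
        n_windows = n_fit
    elif n_windows > n_fit:
        raise ValueError(
            f"fine sequence covers only {n_fit} windows, {n_windows} requested"
        )
    out = np.full(n_windows, UNLABELLED, dtype=object)
    for w in range(n_windows):
        start = w * cfg.hop_s
        end = start + cfg.window_s
        i0 = int(np.ceil(start / step_s - 1e-9))
        i1 = min(int(np.ceil(end / step_s - 1e-9)), len(fine))
        votes: dict = {}
        first_seen: dict = {}
        for i in range(i0, i1):
            lab = fine[i]
            if lab == UNLABELLED:
                continue
            votes[lab] = votes.get(lab, 0) + 1
            first_seen.setdefault(lab, i)
        if votes:
            out[w] = max(votes, key=lambda lab: (votes[lab], -first_seen[lab]))
    return out
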