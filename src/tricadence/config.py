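"""Run configuration: a small YAML schema binding together the discipline
profiles, STFT settings, classifier split settings and epoch lengths.

Unknown keys are rejected so typos fail loudly. Every CLI run logs the
config hash and seed, making stochastic results replayable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import yaml

from .cadence import DisciplineProfile, default_profiles
from .features import StftConfig

__all__ = ["ClassifierConfig", "RunConfig", "load_config", "config_hash"]

_PROFILE_KEYS = {"band", "min_interval_s", "channel", "polarity", "prominence"}
_STFT_KEYS = {
    "window_samples",
    "overlap_samples",
    "sample_rate_hz",
    "prefilter_band",
    "prefilter_order",
}
_CLASSIFIER_KEYS = {"seed", "train_fraction", "n_blocks"}
_TOP_KEYS = {"profiles", "stft", "classifier", "epoch_s", "log_level"}


@dataclass(frozen=True)
class ClassifierConfig:
    seed: int = 0
    train_fraction: float = 0.8
    n_blocks: int = 10


@dataclass(frozen=True)
class RunConfig:
    profiles: Dict[str, DisciplineProfile] = field(default_factory=default_profiles)
    stft: StftConfig = StftConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    epoch_s: float = 60.0
    log_level: str = "INFO"


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load a YAML run config; every section is optional and overrides the
    defaults field-by-field."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    profiles = default_profiles()
    for name, over in (raw.get("profiles") or {}).items():
        if name not in profiles:
            raise ValueError(f"unknown discipline profile {name!r}")
        _check_keys(over, _PROFILE_KEYS, f"profiles.{name}")
        if "band" in over:
            over = {**over, "band": tuple(over["band"])}
        profiles[name] = replace(profiles[name], **over)
    stft_raw = dict(raw.get("stft") or {})
    _check_keys(stft_raw, _STFT_KEYS, "stft")
    if "prefilter_band" in stft_raw and stft_raw["prefilter_band"] is not None:
        stft_raw["prefilter_band"] = tuple(stft_raw["prefilter_band"])
    clf_raw = dict(raw.get("classifier") or {})
    _check_keys(clf_raw, _CLASSIFIER_KEYS, "classifier")
    return RunConfig(
        profiles=profiles,
        stft=StftConfig(**stft_raw),
        classifier=ClassifierConfig(**clf_raw),
        epoch_s=float(raw.get("epoch_s", 60.0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of a run config, for log provenance."""
    payload = {
        "profiles": {
            k: {
                "band": list(p.band),
                "min_interval_s": p.min_interval_s,
                "channel": p.channel,
                "polarity": p.polarity,
                "prominence": p.prominence,
            }
            for k, p in sorted(cfg.profiles.items())
        },
        "stft": {
            "window_samples": cfg.stft.window_samples,
            "overlap_samples": cfg.stft.overlap_samples,
            "sample_rate_hz": cfg.stft.sample_rate_hz,
            "prefilter_band": list(cfg.stft.prefilter_band)
            if cfg.stft.prefilter_band
            else None,
            "prefilter_order": cfg.stft.prefilter_order,
        },
        "classifier": {
            "seed": cfg.classifier.seed,
            "train_fraction": cfg.classifier.train_fraction,
            "n_blocks": cfg.classifier.n_blocks,
        },
        "epoch_s": cfg.epoch_s,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
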