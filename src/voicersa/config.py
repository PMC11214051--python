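"""Pipeline configuration: one flat declarative config with per-stage
sections, two scale presets, and a provenance hash for reproducibility.

The ``paper`` preset carries the full published analysis parameters
(96 stimuli x 40 repetitions, 32 participants, 1 kHz, 5 splits, 50
permutations, 10,000 permutation iterations, z thresholds 1.64 / 1.96,
0.1-30 Hz band, 150 uV rejection).  The ``desk`` preset scales the
simulation down (16 stimuli = 8 speakers x 2 vowels, 8 participants, 20
repetitions, 100 Hz grid, 5 subaveraging permutations, 1,000 iterations) so
the full pipeline runs in minutes while keeping every analysis parameter
that defines the method itself identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "desk_config", "paper_config"]


@dataclass
class PipelineConfig:
    # simulation scale
    n_speakers: int = 8
    vowels: tuple[str, ...] = ("a", "i")
    n_repetitions: int = 20
    n_participants: int = 8
    n_channels: int = 32
    sfreq: float = 100.0
    vigilance_stimuli: int = 0
    vigilance_repetitions: int = 0
    n_blocks: int = 1
    n_raters: int = 20
    rater_noise_sd: float = 1.0
    snr: float = 1.0
    effect_windows: tuple[tuple[float, float], ...] = ((100.0, 300.0), (150.0, 350.0))
    noise_sd_uv: float = 5.0
    outlier_trial_rate: float = 0.0
    # preprocessing
    bad_channel_threshold_sd: float = 4.0
    peak_to_peak_uv: float = 150.0
    low_hz: float = 0.1
    high_hz: float = 30.0
    filter_order: int = 4
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reference_labels: tuple[str, ...] = ("TP9", "TP10")
    # decoding
    n_splits: int = 5
    n_permutations: int = 5
    svm_cost: float = 1.0
    shrinkage_mode: str = "auto"
    # behavior
    max_same_fraction: float = 0.8
    icc_threshold: float = 0.5
    # rsa / inference
    models: tuple[str, ...] = ("M1", "M2", "M3")
    z_threshold_one_sided: float = 1.64
    z_threshold_two_sided: float = 1.96
    n_iterations: int = 1_000
    alpha: float = 0.05
    # global
    seed: int = 0
    preset: str = "desk"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        for key in ("vowels", "reference_labels", "models"):
            if key in kw:
                kw[key] = tuple(kw[key])
        for key in ("baseline_ms",):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "effect_windows" in kw:
            kw["effect_windows"] = tuple(tuple(w) for w in kw["effect_windows"])
        return cls(**kw)


def desk_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Reduced-scale preset used throughout the test suite."""
    return dataclasses.replace(PipelineConfig(seed=seed, preset="desk"), **overrides)


def paper_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Full published-analysis parameters (heavy; hours of compute)."""
    cfg = PipelineConfig(
        n_speakers=32,
        vowels=("a", "i", "u"),
        n_repetitions=40,
        n_participants=32,
        sfreq=1000.0,
        vigilance_stimuli=24,
        vigilance_repetitions=16,
        n_blocks=6,
        n_permutations=50,
        n_iterations=10_000,
        seed=seed,
        preset="paper",
    )
    return dataclasses.replace(cfg, **overrides)
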