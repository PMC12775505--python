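"""Study configuration, validation, and seeded-RNG management.

All stochastic stages derive their seed from a single study seed plus a
stage label, so any stage can be re-run in isolation and reproduce its
output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


def derive_seed(root_seed: int, label: str) -> int:
    """Derive a 31-bit child seed from a root seed and a stage label.

    Deterministic and label-separated: two stages with different labels
    receive statistically independent streams even for equal root seeds.
    """
    digest = hashlib.sha256(f"{int(root_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_rng(root_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, label))


# ---------------------------------------------------------------------------
# Cohort / generator configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Distributions and constants used by the synthetic cohort generator.

    Defaults emulate the acquisition conditions of the study cohort:
    ~7.5-minute supine recordings from four limb-mounted IMUs at 200 Hz plus
    a 33-keypoint pose track at 30 Hz, ~6% of subjects flagged at risk, and
    an annotation mix that yields roughly a 64/36 FM+/FM- window balance
    after segmentation.
    """

    n_subjects: int = 95
    # Recording duration (s): truncated normal.
    duration_mean_s: float = 447.62
    duration_sd_s: float = 112.77
    duration_min_s: float = 137.0
    duration_max_s: float = 936.0
    duration_fixed_s: Optional[float] = None  # overrides the draw if set

    risk_prevalence: float = 6.0 / 95.0

    imu_hz: float = 200.0
    pose_hz: float = 30.0

    # Identity confounds (per subject); applied with strength confound_strength.
    rotation_jitter_deg_sd: float = 10.0   # IMU placement-orientation jitter
    body_scale_sd: float = 0.15            # lognormal sigma of body scale
    amplitude_scale_sd: float = 0.6        # lognormal sigma of movement vigor
    accel_offset_sd: float = 0.5           # m/s^2, per-channel baseline
    gyro_offset_sd: float = 0.2            # rad/s
    pose_offset_sd: float = 0.04           # m, position of infant on the mat
    confound_strength: float = 1.0

    # Effective noise after device-side filtering.
    imu_noise_sd: float = 0.001            # m/s^2 or rad/s
    pose_noise_sd: float = 0.001           # m
    pose_unstable_tracking: bool = False   # extra pose jitter in quiet periods

    # Gross (non-fidgety) movement background.
    gross_accel_amplitude: float = 2.0     # m/s^2
    gross_gyro_amplitude: float = 1.0      # rad/s
    gross_pose_amplitude: float = 0.05     # m

    # Fidgety bursts: band-limited small-amplitude oscillations.
    fm_band_hz: tuple = (2.0, 6.0)
    fm_rel_amplitude: float = 0.2          # relative to gross amplitude
    fm_burst_rate_range: tuple = (30.0, 40.0)   # bursts/minute during FM+
    fm_burst_duration_s: tuple = (1.0, 3.0)
    # Confounded non-fidgety oscillations (present only when confounded):
    distractor_rel_amplitude: float = 0.75  # relative to the FM amplitude
    subject_band_sd_hz: float = 0.6

    # Annotation process.
    fm_fraction: float = 0.636             # target FM time share
    fm_segment_mean_s: float = 15.0
    invalid_fraction: float = 0.05
    invalid_mean_s: float = 3.0

    # Small per-sensor clock offsets recovered by stream alignment.
    imu_clock_offset_sd_s: float = 0.05

    def validate(self) -> "CohortConfig":
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("duration_sd_s", "rotation_jitter_deg_sd", "body_scale_sd",
                     "amplitude_scale_sd", "imu_noise_sd", "pose_noise_sd",
                     "accel_offset_sd", "gyro_offset_sd", "pose_offset_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.risk_prevalence <= 1.0:
            raise ConfigError("risk_prevalence must lie in [0, 1]")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ConfigError("confound_strength must lie in [0, 1]")
        if not 0.0 < self.fm_fraction < 1.0:
            raise ConfigError("fm_fraction must lie in (0, 1)")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ConfigError("invalid_fraction must lie in [0, 1)")
        if self.fm_band_hz[0] <= 0 or self.fm_band_hz[1] <= self.fm_band_hz[0]:
            raise ConfigError("fm_band_hz must be an increasing positive pair")
        return self


@dataclass
class PreprocessConfig:
    target_hz: float = 100.0
    window_s: float = 1.0
    majority_threshold: float = 0.6
    max_lag_s: float = 2.0
    align: bool = True

    def validate(self) -> "PreprocessConfig":
        if self.target_hz <= 0:
            raise ConfigError("target_hz must be positive")
        if self.window_s <= 0:
            raise ConfigError("window_s must be positive")
        if not 0.5 <= self.majority_threshold <= 1.0:
            raise ConfigError("majority_threshold must lie in [0.5, 1]")
        if self.max_lag_s <= 0:
            raise ConfigError("max_lag_s must be positive")
        return self


@dataclass
class HCFConfig:
    search_budget: int = 10

    def validate(self) -> "HCFConfig":
        if self.search_budget < 1:
            raise ConfigError("search_budget must be >= 1")
        return self


@dataclass
class MBCNNTrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64

    def validate(self) -> "MBCNNTrainConfig":
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        return self


@dataclass
class EvalConfig:
    n_folds: int = 5
    ane_k: int = 10
    repetitions: int = 5
    alpha: float = 0.05

    def validate(self) -> "EvalConfig":
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.ane_k < 1:
            raise ConfigError("ane_k must be >= 1")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        return self


@dataclass
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hcf: HCFConfig = field(default_factory=HCFConfig)
    mbcnn: MBCNNTrainConfig = field(default_factory=MBCNNTrainConfig)
    csad: MBCNNTrainConfig = field(default_factory=MBCNNTrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def validate(self) -> "StudyConfig":
        self.cohort.validate()
        self.preprocess.validate()
        self.hcf.validate()
        self.mbcnn.validate()
        self.csad.validate()
        self.evaluation.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _merge_section(cls, data: Any, path: str):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown configuration key: {path}.{key}")
        f = names[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _merge_section(f.type, value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "hcf": HCFConfig,
    "mbcnn": MBCNNTrainConfig,
    "csad": MBCNNTrainConfig,
    "evaluation": EvalConfig,
}


def config_from_dict(data: Optional[dict]) -> StudyConfig:
    """Build a validated :class:`StudyConfig` from a (possibly partial) dict."""
    data = dict(data or {})
    kwargs: dict = {}
    for key in list(data):
        if key in _SECTIONS:
            kwargs[key] = _merge_section(_SECTIONS[key], data.pop(key), key)
        elif key == "seed":
            kwargs["seed"] = int(data.pop(key))
        else:
            raise ConfigError(f"unknown configuration key: {key}")
    return StudyConfig(**kwargs).validate()


def load_config(path) -> StudyConfig:
    """Load a YAML study configuration, merged with defaults and validated."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def dump_config(config: StudyConfig) -> str:
    """Serialize a fully-resolved config to YAML (stable round-trip)."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
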