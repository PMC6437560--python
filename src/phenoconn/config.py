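"""Study and cohort configuration.

A study is two cohorts observed under different phone-sampling regimes
(continuous screen-time logging vs a duty-cycled 1-min-per-10-min schedule)
plus a shared imaging/analysis parameter set.  Defaults reproduce the study
conditions: framewise-displacement threshold 0.25 mm, passband
0.009-0.08 Hz, 4 mm seed sphere at MNI (0, 25, -10), 20-day / 16-hour
phone data-quality rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SAMPLING_MODES = ("continuous", "duty_cycled")

#: PHQ-8 severity cutpoints (Kroenke scheme): total -> category.
SEVERITY_CUTPOINTS: dict[str, tuple[int, int]] = {
    "minimal": (0, 4),
    "mild": (5, 9),
    "moderate": (10, 14),
    "moderately_severe": (15, 19),
    "severe": (20, 24),
}


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


@dataclass
class CohortConfig:
    """Generation parameters for one synthetic cohort.

    ``effect_r`` is the target across-subject correlation between the
    behavioral covariate (mean daily unlock minutes) and planted
    seed-target connectivity strength.  ``icc_consistency`` in [0, 1]
    controls how stable a subject's day/evening/night feature profile is
    from day to day (1 -> identical profiles, realized ICC near 1).
    """

    n_subjects: int = 80
    sampling_mode: str = "continuous"
    effect_r: float = 0.5
    icc_consistency: float = 0.5
    missing_day_rate: float = 0.1
    motion_spike_rate: float = 0.03
    n_frames: int = 240
    tr_seconds: float = 2.5
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 3.0
    rng_seed: int = 0
    # phone-stream model (session-level distributions are an assumption of
    # the generator; the study describes none)
    n_days: int = 35
    unlock_mean_minutes: float = 180.0
    unlock_per_severity_minutes: float = 40.0
    unlock_noise_sd_minutes: float = 25.0
    still_mean_minutes: float = 600.0
    still_profile_sd_minutes: float = 80.0
    conversation_rate: float = 0.2
    survey_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.sampling_mode not in SAMPLING_MODES:
            raise ConfigurationError(
                f"sampling_mode must be one of {SAMPLING_MODES}, got {self.sampling_mode!r}"
            )
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if not -1.0 < self.effect_r < 1.0:
            raise ConfigurationError("effect_r must lie in (-1, 1)")
        for name in ("icc_consistency", "missing_day_rate",
                     "motion_spike_rate", "conversation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_frames <= 0:
            raise ConfigurationError("n_frames must be positive")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 8 for g in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 integers, each >= 8")
        if self.voxel_mm <= 0:
            raise ConfigurationError("voxel_mm must be positive")


@dataclass
class StudyConfig:
    """Two cohorts plus pipeline parameters for an end-to-end study run."""

    cohort1: CohortConfig = field(default_factory=lambda: CohortConfig(
        sampling_mode="continuous", tr_seconds=2.5, n_frames=240, rng_seed=1))
    cohort2: CohortConfig = field(default_factory=lambda: CohortConfig(
        sampling_mode="duty_cycled", tr_seconds=1.19, n_frames=605, rng_seed=2))
    fd_threshold_mm: float = 0.25
    band_hz: tuple[float, float] = (0.009, 0.08)
    seed_mni: tuple[float, float, float] = (0.0, 25.0, -10.0)
    seed_radius_mm: float = 4.0
    voxel_p: float = 0.01
    corrected_alpha: float = 0.05
    cluster_iterations: int = 1000
    min_days: int = 20
    min_coverage_hours: float = 16.0
    output_dir: str = "results/study"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.band_hz = tuple(float(b) for b in self.band_hz)
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ConfigurationError("band_hz must satisfy 0 < f_lo < f_hi")
        if not 0 < self.voxel_p < 1 or not 0 < self.corrected_alpha < 1:
            raise ConfigurationError("voxel_p and corrected_alpha must lie in (0, 1)")
        if self.fd_threshold_mm <= 0 or self.seed_radius_mm <= 0:
            raise ConfigurationError("fd_threshold_mm and seed_radius_mm must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from YAML; missing keys fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohorts = {}
    for key in ("cohort1", "cohort2"):
        if key in raw:
            cohorts[key] = CohortConfig(**raw.pop(key))
    return StudyConfig(**cohorts, **raw)


def save_study_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
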