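"""Shared configuration for the numbered analysis scripts.

A desk-scale two-cohort study: 60 subjects per cohort, 30 study days,
12 x 14 x 12 voxel grid at 3 mm, 150-frame runs, planted brain-behavior
effect r = 0.6.  Cohort 1 samples the phone continuously; cohort 2 is
duty-cycled (1 min per 10-min cycle, up to 3 min on conversation).
"""

from pathlib import Path

from phenoconn.config import CohortConfig, StudyConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

COMMON = dict(n_subjects=60, n_days=30, grid_shape=(12, 14, 12),
              n_frames=150, tr_seconds=2.5, missing_day_rate=0.08,
              motion_spike_rate=0.03, effect_r=0.6, icc_consistency=0.6)


def study_config() -> StudyConfig:
    return StudyConfig(
        cohort1=CohortConfig(rng_seed=101, sampling_mode="continuous", **COMMON),
        cohort2=CohortConfig(rng_seed=202, sampling_mode="duty_cycled", **COMMON),
        cluster_iterations=1000, rng_seed=11,
        output_dir=str(RESULTS / "study"))
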