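"""Study-condition evaluation runs: calibration and parameter recovery.

These are the package's own end-to-end checks, run both by the test suite
and by ``scripts/acceptance.py``:

* ``null_calibration_check`` — many small independent cohorts generated with
  no brain-behavior effect, pushed through the full generator -> denoising ->
  group-correlation path; reports the voxelwise false-positive fraction at
  p < 0.05 and the corrected cluster-level false-positive rate.
* ``effect_recovery_replicates`` — repeated two-cohort studies with a
  planted effect (effect_r = 0.5, 80 subjects per cohort); reports how well
  the group correlation at the planted target region recovers the effect and
  how often the cohort-1-masked cohort-2 replication covers at least half of
  the planted region.

Problem sizes are scaled for desk-class hardware (small grids, 150-frame
runs — the shortest satisfying the 5-minute retention rule at TR 2.5 s);
the replicate loop correlates seed maps against the generator's latent
behavior covariate directly (the quantity the phone features estimate),
while the phone -> feature path is exercised end to end by
``workbench.run_study``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import groupstats as gs
from .config import CohortConfig
from .rsfc import process_run, subject_inclusion
from .synthgen import draw_subjects, generate_bold_run, make_masks, region_voxels


def _derive_seed(master: int, label: str, k: int = 0) -> int:
    return (master * 1000003 + zlib.crc32(label.encode()) + 7919 * k) % (2 ** 31)


def _cohort_seed_maps(ccfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seed maps + behavior covariate for one generated cohort.

    The study's data-retention rules are enforced (>= 50 uncensored frames
    per run, >= 5 min per subject); they bound the across-subject spread of
    map measurement noise, which the equal-weight group correlation
    assumes.
    """
    subs = draw_subjects(ccfg)
    stack, beh = [], []
    for s in subs:
        run, _ = generate_bold_run(s, ccfg)
        sm, censor = process_run(run)
        if sm is None or not subject_inclusion([censor], ccfg.tr_seconds):
            continue
        stack.append(sm.z)
        beh.append(s.latent_severity)
    return np.stack(stack), np.array(beh)


@dataclass
class NullCalibrationReport:
    voxel_fraction_p05: float
    cluster_fpr: float
    n_datasets: int
    extent_threshold: int
    fwhm_mm: float
    fractions: list = field(default_factory=list)


def null_calibration_check(seed: int, n_datasets: int = 200,
                           n_subjects: int = 12, n_frames: int = 150,
                           grid_shape=(20, 24, 20), voxel_p: float = 0.01,
                           corrected_alpha: float = 0.05,
                           calibration_iterations: int = 2000
                           ) -> NullCalibrationReport:
    """Null false-positive rates over independent no-effect cohorts."""
    base = dict(n_subjects=n_subjects, effect_r=0.0, grid_shape=grid_shape,
                n_frames=n_frames, tr_seconds=2.5)
    pilot_cfg = CohortConfig(rng_seed=_derive_seed(seed, "null-pilot"), **base)
    seedv, target, affine = region_voxels(pilot_cfg)
    brain = make_masks(pilot_cfg, seedv, target)["whole_brain"]
    pilot_stack, _ = _cohort_seed_maps(pilot_cfg)
    fwhm = gs.estimate_fwhm(pilot_stack - pilot_stack.mean(axis=0),
                            pilot_cfg.voxel_mm, mask=brain)
    cal = gs.cluster_extent_threshold(
        brain, fwhm, pilot_cfg.voxel_mm, voxel_p=voxel_p,
        corrected_alpha=corrected_alpha, n_iterations=calibration_iterations,
        rng_seed=_derive_seed(seed, "null-cal"),
        n_subjects=len(pilot_stack))
    fps = 0
    fractions = []
    for i in range(n_datasets):
        ccfg = CohortConfig(rng_seed=_derive_seed(seed, "null-data", i), **base)
        stack, beh = _cohort_seed_maps(ccfg)
        res = gs.voxelwise_correlate(stack, beh, brain, affine=affine,
                                     voxel_mm=ccfg.voxel_mm)
        fractions.append(float((res.p_map[brain] < 0.05).mean()))
        table = gs.find_clusters(res, voxel_p=voxel_p, calibration=cal)
        if len(table) and table["passed_correction"].astype(bool).any():
            fps += 1
    return NullCalibrationReport(
        voxel_fraction_p05=float(np.mean(fractions)),
        cluster_fpr=fps / n_datasets, n_datasets=n_datasets,
        extent_threshold=cal.extent_threshold, fwhm_mm=float(fwhm),
        fractions=fractions)


@dataclass
class RecoveryReport:
    mean_target_recovery_r: float
    recovery_values: list
    replication_success_rate: float
    overlap_fractions: list
    n_replicates: int


def _one_recovery_replicate(seed1: int, seed2: int, cal, base: dict
                            ) -> tuple[float, float]:
    """(overlap fraction of planted region, cohort-1 target recovery r)."""
    c1 = CohortConfig(rng_seed=seed1, **base)
    c2 = CohortConfig(rng_seed=seed2, sampling_mode="duty_cycled", **base)
    seedv, target, affine = region_voxels(c1)
    brain = make_masks(c1, seedv, target)["whole_brain"]
    s1, b1 = _cohort_seed_maps(c1)
    s2, b2 = _cohort_seed_maps(c2)
    r1 = gs.voxelwise_correlate(s1, b1, brain, affine=affine)
    r2 = gs.voxelwise_correlate(s2, b2, brain, affine=affine)
    tv = tuple(target.T)
    recovery = float(np.corrcoef(b1, s1[:, tv[0], tv[1], tv[2]].mean(axis=1))[0, 1])
    clusters1 = gs.find_clusters(r1, voxel_p=0.01, calibration=cal)
    mask1 = gs.cluster_mask(r1, clusters1, voxel_p=0.01)
    if not mask1.any():
        return 0.0, recovery
    rep_table, _rep_cal = gs.mask_replicate(
        r2, mask1, voxel_p=0.01, corrected_alpha=0.05,
        fwhm_mm=cal.fwhm_mm, n_iterations=500,
        rng_seed=_derive_seed(seed1, "rep-cal"), positive_only=True)
    restricted = gs.GroupResult(
        r_map=r2.r_map, t_map=r2.t_map, p_map=r2.p_map,
        n_subjects=r2.n_subjects, covariate_name=r2.covariate_name,
        analysis_mask=r2.analysis_mask & mask1, affine=affine,
        voxel_mm=c2.voxel_mm)
    rep_mask = gs.cluster_mask(restricted, rep_table, voxel_p=0.01,
                               positive_only=True)
    truth_mask = np.zeros_like(mask1)
    truth_mask[tv] = True
    return float((rep_mask & truth_mask).sum() / truth_mask.sum()), recovery


def effect_recovery_replicates(seed: int, n_replicates: int = 50,
                               n_subjects: int = 80, effect_r: float = 0.5,
                               n_frames: int = 150,
                               grid_shape=(12, 14, 12)) -> RecoveryReport:
    """Planted-effect recovery and masked cross-cohort replication."""
    base = dict(n_subjects=n_subjects, effect_r=effect_r,
                grid_shape=grid_shape, n_frames=n_frames, tr_seconds=2.5)
    pilot = CohortConfig(rng_seed=_derive_seed(seed, "rec-pilot"), **base)
    seedv, target, affine = region_voxels(pilot)
    brain = make_masks(pilot, seedv, target)["whole_brain"]
    pilot_stack, _ = _cohort_seed_maps(
        CohortConfig(rng_seed=_derive_seed(seed, "rec-pilot"),
                     **{**base, "n_subjects": 20, "effect_r": 0.0}))
    fwhm = gs.estimate_fwhm(pilot_stack - pilot_stack.mean(axis=0),
                            pilot.voxel_mm, mask=brain)
    cal = gs.cluster_extent_threshold(
        brain, fwhm, pilot.voxel_mm, voxel_p=0.01, corrected_alpha=0.05,
        n_iterations=1000, rng_seed=_derive_seed(seed, "rec-cal"),
        n_subjects=n_subjects)
    overlaps, recoveries = [], []
    for i in range(n_replicates):
        ov, rec = _one_recovery_replicate(
            _derive_seed(seed, "rec-c1", i), _derive_seed(seed, "rec-c2", i),
            cal, base)
        overlaps.append(ov)
        recoveries.append(rec)
    success = float(np.mean([ov >= 0.5 for ov in overlaps]))
    return RecoveryReport(
        mean_target_recovery_r=float(np.mean(recoveries)),
        recovery_values=recoveries,
        replication_success_rate=success,
        overlap_fractions=overlaps, n_replicates=n_replicates)
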