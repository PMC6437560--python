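"""End-to-end study orchestration.

``run_study`` drives simulate -> phone features -> circadian ICC -> survey
scoring -> per-subject RSFC seed maps -> group correlation with cluster
correction -> cohort-1-masked cohort-2 replication -> overlap report, and
assembles a machine-readable manifest (verbatim parameters, per-stage
subject attrition, content hashes) from which any run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circadian, groupstats, io, sensing, surveys
from .config import StudyConfig
from .rsfc import process_run, subject_inclusion
from .synthgen import CohortData, generate_cohort


@dataclass
class CohortResults:
    name: str
    data: CohortData
    daily_unlock: dict[str, pd.DataFrame]
    mean_unlock: dict[str, float]          # included subjects only
    epoch_tables: dict[str, pd.DataFrame]  # still feature, per subject
    icc_scores: pd.DataFrame
    survey_scores: pd.DataFrame
    seed_maps: dict[str, np.ndarray]       # Fisher-z volumes, included subjects
    n_uncensored: dict[str, int]
    attrition: dict[str, int]
    group: groupstats.GroupResult | None = None
    clusters: pd.DataFrame | None = None
    calibration: groupstats.NullCalibration | None = None
    fwhm_mm: float | None = None


@dataclass
class StudyReport:
    config: StudyConfig
    cohorts: dict[str, CohortResults]
    replication: pd.DataFrame | None
    replication_calibration: groupstats.NullCalibration | None
    overlap: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _stage_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from a label so adding a
    stage never perturbs earlier stages."""
    import zlib
    return (master * 1000003 + zlib.crc32(label.encode())) % (2 ** 31)


def _phone_features(cohort: CohortData, cfg: StudyConfig) -> tuple[dict, dict, dict]:
    """Per-subject daily unlock tables (duty-cycle upscaled), subject means,
    and still-feature epoch tables."""
    daily: dict[str, pd.DataFrame] = {}
    means: dict[str, float] = {}
    epoch_tables: dict[str, pd.DataFrame] = {}
    duty = cohort.config.sampling_mode == "duty_cycled"
    for sub in cohort.subjects:
        ev = cohort.events[cohort.events["subject_id"] == sub.subject_id]
        if len(ev) == 0:
            continue
        sched = cohort.schedules[cohort.schedules["subject_id"] == sub.subject_id]
        unlock_ep = sensing.epoch_partition(ev, "unlock",
                                            min_coverage_hours=cfg.min_coverage_hours)
        still_ep = sensing.epoch_partition(ev, "still",
                                           min_coverage_hours=cfg.min_coverage_hours)
        if duty:
            unlock_ep = sensing.coverage_upscale(unlock_ep, sched, "unlock_minutes")
            still_ep = sensing.coverage_upscale(still_ep, sched, "still_minutes")
        epoch_tables[sub.subject_id] = still_ep
        day_tab = (unlock_ep.groupby("day", as_index=False)
                   .agg(unlock_minutes=("unlock_minutes", "sum"),
                        coverage_hours=("coverage_hours", "first")))
        day_tab["day_valid"] = day_tab["coverage_hours"] >= cfg.min_coverage_hours
        daily[sub.subject_id] = day_tab
        mean = sensing.subject_mean_unlock(day_tab, min_days=cfg.min_days)
        if mean is not None:
            means[sub.subject_id] = mean
    return daily, means, epoch_tables


def _seed_maps(cohort: CohortData, cfg: StudyConfig) -> tuple[dict, dict]:
    maps: dict[str, np.ndarray] = {}
    n_unc: dict[str, int] = {}
    for sub in cohort.subjects:
        run = cohort.bold_run(sub.subject_id)
        sm, censor = process_run(
            run, fd_threshold=cfg.fd_threshold_mm, band=cfg.band_hz,
            seed_center_mni=cfg.seed_mni, seed_radius_mm=cfg.seed_radius_mm)
        if sm is None:
            continue
        if not subject_inclusion([censor], run.tr_seconds):
            continue
        maps[sub.subject_id] = sm.z
        n_unc[sub.subject_id] = sm.n_uncensored_frames
    return maps, n_unc


def _run_cohort(name: str, cohort: CohortData, cfg: StudyConfig) -> CohortResults:
    daily, means, epoch_tables = _phone_features(cohort, cfg)
    icc = circadian.cohort_similarity_table(epoch_tables, "still",
                                            min_days=cfg.min_days)
    scores = surveys.score_survey_table(cohort.surveys)
    maps, n_unc = _seed_maps(cohort, cfg)
    attrition = {
        "enrolled": cohort.config.n_subjects,
        "phone_min_days": len(means),
        "icc_min_days": int(len(icc)),
        "rsfc_quality": len(maps),
        "analysis": len(set(means) & set(maps)),
    }
    return CohortResults(name=name, data=cohort, daily_unlock=daily,
                         mean_unlock=means, epoch_tables=epoch_tables,
                         icc_scores=icc, survey_scores=scores,
                         seed_maps=maps, n_uncensored=n_unc,
                         attrition=attrition)


def _group_stage(res: CohortResults, cfg: StudyConfig, seed: int,
                 calibration: groupstats.NullCalibration | None = None
                 ) -> CohortResults:
    subjects = sorted(set(res.mean_unlock) & set(res.seed_maps))
    stack = np.stack([res.seed_maps[s] for s in subjects])
    cov = np.array([res.mean_unlock[s] for s in subjects])
    run_cfg = res.data.config
    from .synthgen import region_voxels
    _, _, affine = region_voxels(run_cfg)
    mask = res.data.bold_run(subjects[0]).masks["whole_brain"] if subjects else None
    group = groupstats.voxelwise_correlate(
        stack, cov, mask, covariate_name="mean_unlock_minutes",
        affine=affine, voxel_mm=run_cfg.voxel_mm)
    resid = stack - stack.mean(axis=0)
    fwhm = groupstats.estimate_fwhm(resid, run_cfg.voxel_mm, mask=mask)
    group.metadata["fwhm_mm"] = fwhm
    if calibration is None:
        calibration = groupstats.cluster_extent_threshold(
            mask, fwhm, run_cfg.voxel_mm, voxel_p=cfg.voxel_p,
            corrected_alpha=cfg.corrected_alpha,
            n_iterations=cfg.cluster_iterations, rng_seed=seed,
            n_subjects=group.n_subjects)
    clusters = groupstats.find_clusters(group, voxel_p=cfg.voxel_p,
                                        calibration=calibration)
    res.group = group
    res.clusters = clusters
    res.calibration = calibration
    res.fwhm_mm = fwhm
    return res


def _hash_obj(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, pd.DataFrame):
        h.update(obj.to_csv(index=False).encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_study(cfg: StudyConfig, write_outputs: bool = True) -> StudyReport:
    """Run the full two-cohort workflow and return a StudyReport.

    When ``write_outputs`` is set, feature tables, score tables, cluster
    tables, group maps and the manifest are written under
    ``cfg.output_dir``.
    """
    cohorts = {}
    for name, ccfg in (("cohort1", cfg.cohort1), ("cohort2", cfg.cohort2)):
        data = generate_cohort(ccfg, prefix={"cohort1": "C1S", "cohort2": "C2S"}[name])
        cohorts[name] = _run_cohort(name, data, cfg)

    c1 = _group_stage(cohorts["cohort1"], cfg, _stage_seed(cfg.rng_seed, "cluster-c1"))
    c2 = _group_stage(cohorts["cohort2"], cfg, _stage_seed(cfg.rng_seed, "cluster-c2"))

    replication = None
    rep_calib = None
    overlap = None
    mask_a = groupstats.cluster_mask(c1.group, c1.clusters, voxel_p=cfg.voxel_p)
    if mask_a.any():
        replication, rep_calib = groupstats.mask_replicate(
            c2.group, mask_a, voxel_p=cfg.voxel_p,
            corrected_alpha=cfg.corrected_alpha, fwhm_mm=c2.fwhm_mm,
            n_iterations=cfg.cluster_iterations,
            rng_seed=_stage_seed(cfg.rng_seed, "cluster-replication"))
        rep_mask = groupstats.cluster_mask(
            groupstats.GroupResult(
                r_map=c2.group.r_map, t_map=c2.group.t_map, p_map=c2.group.p_map,
                n_subjects=c2.group.n_subjects, covariate_name=c2.group.covariate_name,
                analysis_mask=c2.group.analysis_mask & mask_a,
                affine=c2.group.affine, voxel_mm=c2.group.voxel_mm),
            replication, voxel_p=cfg.voxel_p, positive_only=True)
        truth_mask = np.zeros_like(mask_a)
        tv = cohorts["cohort1"].data.ground_truth.target_region_voxels
        truth_mask[tuple(tv.T)] = True
        overlap = groupstats.overlap_report(
            {"cohort1_cluster": mask_a, "cohort2_replication": rep_mask,
             "planted_target": truth_mask}, affine=c1.group.affine)

    manifest = {
        "parameters": cfg.to_dict(),
        "attrition": {n: c.attrition for n, c in cohorts.items()},
        "stage_seeds": {lbl: _stage_seed(cfg.rng_seed, lbl)
                        for lbl in ("cluster-c1", "cluster-c2", "cluster-replication")},
        "hashes": {
            "cohort1_events": _hash_obj(cohorts["cohort1"].data.events),
            "cohort2_events": _hash_obj(cohorts["cohort2"].data.events),
            "cohort1_group_t": _hash_obj(c1.group.t_map),
            "cohort2_group_t": _hash_obj(c2.group.t_map),
            "cohort1_clusters": _hash_obj(c1.clusters),
            "replication": _hash_obj(replication if replication is not None
                                     else pd.DataFrame()),
        },
    }
    report = StudyReport(config=cfg, cohorts=cohorts, replication=replication,
                         replication_calibration=rep_calib, overlap=overlap,
                         manifest=manifest)
    if write_outputs:
        _write_outputs(report)
    return report


def _write_outputs(report: StudyReport) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, c in report.cohorts.items():
        d = out / name
        d.mkdir(exist_ok=True)
        io.write_events_tsv(c.data.events, d / "events.tsv")
        io.write_table_tsv(c.data.schedules, d / "sampling_schedule.tsv")
        io.write_table_tsv(c.data.surveys, d / "survey_responses.tsv")
        io.write_table_tsv(c.icc_scores, d / "circadian_icc.tsv")
        io.write_table_tsv(c.survey_scores, d / "survey_scores.tsv")
        mean_tab = pd.DataFrame(sorted(c.mean_unlock.items()),
                                columns=["subject_id", "mean_unlock_minutes"])
        io.write_table_tsv(mean_tab, d / "mean_unlock.tsv")
        if c.group is not None:
            io.write_nifti(c.group.r_map, c.group.affine, d / "group_r.nii")
            io.write_nifti(c.group.t_map, c.group.affine, d / "group_t.nii")
            io.write_nifti(c.group.p_map, c.group.affine, d / "group_p.nii")
            io.write_table_tsv(c.clusters, d / "clusters.tsv")
            with open(d / "cluster_calibration.json", "w") as fh:
                json.dump(c.calibration.to_dict(), fh, indent=2)
        files[name] = sorted(p.name for p in d.iterdir())
    if report.replication is not None:
        io.write_table_tsv(report.replication, out / "replication_clusters.tsv")
        with open(out / "replication_calibration.json", "w") as fh:
            json.dump(report.replication_calibration.to_dict(), fh, indent=2)
    if report.overlap is not None:
        io.write_table_tsv(report.overlap, out / "overlap_report.tsv")
    report.manifest["files"] = files
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
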