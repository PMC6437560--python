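"""Cross-cohort replication: mask cohort 2's unlock-duration map with the
cohort-1 cluster, re-calibrate the extent threshold within the mask, and
report voxel overlap with the planted target region.

Writes results/group/replication_clusters.tsv and overlap_report.tsv.
"""

import numpy as np
from scipy import stats
from studyconf import RESULTS, study_config

from phenoconn import groupstats as gs, io
from phenoconn.synthgen import make_masks, region_voxels

cfg = study_config()
out = RESULTS / "group"


def load_result(name, ccfg):
    t_map, affine = io.read_nifti(out / f"{name}_t.nii")
    r_map, _ = io.read_nifti(out / f"{name}_r.nii")
    t_map, r_map = np.asarray(t_map, float), np.asarray(r_map, float)
    seedv, target, _ = region_voxels(ccfg)
    brain = make_masks(ccfg, seedv, target)["whole_brain"]
    n = int(io.read_table_tsv(out / f"{name}_clusters.tsv").attrs.get("n", 0)) or None
    # subject count from the feature table (df = N - 2)
    means = io.read_table_tsv(RESULTS / "features" / f"{name}_mean_unlock.tsv")
    n = int(means["included"].sum())
    res = gs.GroupResult(r_map=r_map, t_map=t_map,
                         p_map=2 * stats.t.sf(np.abs(t_map), n - 2),
                         n_subjects=n, covariate_name="mean_unlock_minutes",
                         analysis_mask=brain, affine=affine,
                         voxel_mm=ccfg.voxel_mm)
    return res, target


res1, target = load_result("cohort1", cfg.cohort1)
res2, _ = load_result("cohort2", cfg.cohort2)
clusters1 = io.read_table_tsv(out / "cohort1_clusters.tsv")
mask1 = gs.cluster_mask(res1, clusters1, voxel_p=cfg.voxel_p)

if not mask1.any():
    print("cohort 1 produced no corrected cluster; nothing to replicate")
    raise SystemExit(0)

rep, rep_cal = gs.mask_replicate(res2, mask1, voxel_p=cfg.voxel_p,
                                 corrected_alpha=cfg.corrected_alpha,
                                 n_iterations=cfg.cluster_iterations,
                                 rng_seed=cfg.rng_seed + 1, positive_only=True)
io.write_table_tsv(rep, out / "replication_clusters.tsv")

restricted = gs.GroupResult(r_map=res2.r_map, t_map=res2.t_map,
                            p_map=res2.p_map, n_subjects=res2.n_subjects,
                            covariate_name=res2.covariate_name,
                            analysis_mask=res2.analysis_mask & mask1,
                            affine=res2.affine, voxel_mm=res2.voxel_mm)
rep_mask = gs.cluster_mask(restricted, rep, voxel_p=cfg.voxel_p,
                           positive_only=True)
truth = np.zeros_like(mask1)
truth[tuple(target.T)] = True
report = gs.overlap_report({"cohort1_cluster": mask1,
                            "cohort2_replication": rep_mask,
                            "planted_target": truth}, affine=res1.affine)
io.write_table_tsv(report, out / "overlap_report.tsv")

passed = rep[rep["passed_correction"].astype(bool)]
ov = report.set_index("masks")
print(f"cohort-1 mask: {int(mask1.sum())} voxels; replication clusters: "
      f"{len(rep)} ({len(passed)} pass correction within the mask, "
      f"k>={rep_cal.extent_threshold})")
print(f"replication voxels: {int(rep_mask.sum())}; overlap with planted "
      f"target: {int(ov.loc['cohort2_replication & planted_target', 'overlap_voxels'])}"
      f"/{int(truth.sum())} voxels")
print(report.to_string(index=False))
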