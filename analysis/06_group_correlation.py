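"""Correlate seed maps with mean unlock duration across subjects, per
cohort, and apply Monte-Carlo cluster-extent correction.

Writes group r/t/p maps, cluster tables and the null calibration under
results/group/.
"""

import json

import numpy as np
from studyconf import RESULTS, study_config

from phenoconn import groupstats as gs, io
from phenoconn.synthgen import make_masks, region_voxels

cfg = study_config()
out = RESULTS / "group"
out.mkdir(parents=True, exist_ok=True)

for name, ccfg in (("cohort1", cfg.cohort1), ("cohort2", cfg.cohort2)):
    means = io.read_table_tsv(RESULTS / "features" / f"{name}_mean_unlock.tsv")
    means = means[means["included"]].set_index("subject_id")["mean_unlock_minutes"]
    stack, cov, used = [], [], []
    for sid, m in means.items():
        p = RESULTS / "seedmaps" / f"{sid}_seedmap.nii"
        if not p.exists():
            continue
        z, affine = io.read_nifti(p)
        stack.append(np.asarray(z, float))
        cov.append(float(m))
        used.append(sid)
    stack, cov = np.stack(stack), np.array(cov)
    seedv, target, affine = region_voxels(ccfg)
    brain = make_masks(ccfg, seedv, target)["whole_brain"]
    res = gs.voxelwise_correlate(stack, cov, brain,
                                 covariate_name="mean_unlock_minutes",
                                 affine=affine, voxel_mm=ccfg.voxel_mm)
    fwhm = gs.estimate_fwhm(stack - stack.mean(axis=0), ccfg.voxel_mm, mask=brain)
    cal = gs.cluster_extent_threshold(brain, fwhm, ccfg.voxel_mm,
                                      voxel_p=cfg.voxel_p,
                                      corrected_alpha=cfg.corrected_alpha,
                                      n_iterations=cfg.cluster_iterations,
                                      rng_seed=cfg.rng_seed,
                                      n_subjects=len(used))
    clusters = gs.find_clusters(res, voxel_p=cfg.voxel_p, calibration=cal)
    io.write_nifti(res.t_map, affine, out / f"{name}_t.nii")
    io.write_nifti(res.r_map, affine, out / f"{name}_r.nii")
    io.write_table_tsv(clusters, out / f"{name}_clusters.tsv")
    with open(out / f"{name}_calibration.json", "w") as fh:
        json.dump(cal.to_dict(), fh, indent=2)
    passed = clusters[clusters["passed_correction"].astype(bool)]
    top = clusters.iloc[0] if len(clusters) else None
    print(f"{name}: n={len(used)}, df={res.df}, FWHM {fwhm:.1f} mm, "
          f"extent threshold k>={cal.extent_threshold}; "
          f"{len(clusters)} clusters, {len(passed)} pass correction"
          + (f"; largest {int(top['extent_voxels'])} voxels "
             f"({top['volume_mm3']:.0f} mm^3), peak t={top['peak_t']:.2f} at "
             f"({top['peak_x_mm']:.0f}, {top['peak_y_mm']:.0f}, "
             f"{top['peak_z_mm']:.0f})" if top is not None else ""))
print(f"group results under {out}")
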