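"""Denoise each subject's BOLD run and compute subgenual-seed maps.

The BOLD runs are regenerated deterministically from the study config
(stream: FD censoring at 0.25 mm -> 36-parameter Volterra + tissue nuisance
regression on uncensored frames -> Lomb-Scargle reconstitution of censored
frames -> 0.009-0.08 Hz band-pass -> correlation on uncensored frames from
the 4 mm sphere at MNI (0, 25, -10)).  Writes per-subject Fisher-z seed
maps under results/seedmaps/.
"""

import json

from studyconf import RESULTS, study_config

from phenoconn import io
from phenoconn.rsfc import process_run, subject_inclusion
from phenoconn.synthgen import generate_cohort

cfg = study_config()
out = RESULTS / "seedmaps"
out.mkdir(parents=True, exist_ok=True)

for name, ccfg, prefix in (("cohort1", cfg.cohort1, "C1S"),
                           ("cohort2", cfg.cohort2, "C2S")):
    cohort = generate_cohort(ccfg, prefix=prefix)
    kept, dropped = 0, 0
    for sub in cohort.subjects:
        run = cohort.bold_run(sub.subject_id)
        sm, censor = process_run(run, fd_threshold=cfg.fd_threshold_mm,
                                 band=cfg.band_hz, seed_center_mni=cfg.seed_mni,
                                 seed_radius_mm=cfg.seed_radius_mm)
        if sm is None or not subject_inclusion([censor], run.tr_seconds):
            dropped += 1
            continue
        io.write_nifti(sm.z, run.affine, out / f"{sub.subject_id}_seedmap.nii")
        with open(out / f"{sub.subject_id}_seedmap.json", "w") as fh:
            json.dump({"subject_id": sm.subject_id,
                       "n_uncensored": sm.n_uncensored_frames,
                       "stage_log": sm.stage_log}, fh)
        kept += 1
    print(f"{name}: {kept} seed maps written, {dropped} subjects dropped by "
          "the 50-frame/5-minute motion rules")
print(f"seed maps under {out}")
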