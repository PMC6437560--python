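"""Score circadian similarity: NaN-tolerant consistency ICC of each
subject's day x epoch stillness profile (and location counts).

Writes per-subject scores under results/features/.
"""

from studyconf import RESULTS, study_config

from phenoconn import circadian, io

cfg = study_config()
out = RESULTS / "features"

for name in ("cohort1", "cohort2"):
    tab = io.read_table_tsv(out / f"{name}_epoch_features.tsv")
    tables = {sid: grp for sid, grp in tab.groupby("subject_id")}
    scores = circadian.cohort_similarity_table(tables, "still",
                                               min_days=cfg.min_days)
    io.write_table_tsv(scores, out / f"{name}_circadian_icc.tsv")
    print(f"{name}: {len(scores)}/{len(tables)} subjects scored; "
          f"mean stillness ICC {scores['icc'].mean():.3f} "
          f"(generator consistency {cfg.cohort1.icc_consistency})")
print(f"ICC tables under {out}")
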