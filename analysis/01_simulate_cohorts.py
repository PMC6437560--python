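"""Simulate the two synthetic cohorts and write their raw data tables.

Writes per-cohort phone event streams, sampling schedules, survey responses
and the generator's ground truth under results/data/.
"""

from studyconf import RESULTS, study_config

from phenoconn import io
from phenoconn.synthgen import generate_cohort

cfg = study_config()
out = RESULTS / "data"
out.mkdir(parents=True, exist_ok=True)

for name, ccfg, prefix in (("cohort1", cfg.cohort1, "C1S"),
                           ("cohort2", cfg.cohort2, "C2S")):
    cohort = generate_cohort(ccfg, prefix=prefix)
    io.write_events_tsv(cohort.events, out / f"{name}_events.tsv")
    io.write_table_tsv(cohort.schedules, out / f"{name}_schedule.tsv")
    io.write_table_tsv(cohort.surveys, out / f"{name}_surveys.tsv")
    io.write_table_tsv(cohort.ground_truth.table, out / f"{name}_ground_truth.tsv")
    n_days = cohort.events["start"].dt.normalize().nunique()
    print(f"{name}: {ccfg.n_subjects} subjects, {len(cohort.events)} events "
          f"over {n_days} calendar days, sampling={ccfg.sampling_mode}")
print(f"raw tables under {out}")
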