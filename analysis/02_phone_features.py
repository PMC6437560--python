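"""Extract daily unlock duration and epoch features from the phone streams.

Applies the 16-hour quality-coverage rule per day and the 20-valid-day rule
per subject; cohort 2's duty-cycled observations are upscaled by the
realized coverage fraction.  Writes results/features/.
"""

import pandas as pd
from studyconf import RESULTS, study_config

from phenoconn import io, sensing

cfg = study_config()
data = RESULTS / "data"
out = RESULTS / "features"
out.mkdir(parents=True, exist_ok=True)

for name in ("cohort1", "cohort2"):
    events = io.read_events_tsv(data / f"{name}_events.tsv")
    schedule = io.read_table_tsv(data / f"{name}_schedule.tsv")
    duty = name == "cohort2"
    rows, epoch_frames = [], []
    for sid, ev in events.groupby("subject_id"):
        unlock = sensing.epoch_partition(ev, "unlock",
                                         min_coverage_hours=cfg.min_coverage_hours)
        still = sensing.epoch_partition(ev, "still",
                                        min_coverage_hours=cfg.min_coverage_hours)
        if duty:
            sched = schedule[schedule["subject_id"] == sid]
            unlock = sensing.coverage_upscale(unlock, sched, "unlock_minutes")
            still = sensing.coverage_upscale(still, sched, "still_minutes")
        merged = unlock.merge(still[["day", "epoch", "still_minutes"]],
                              on=["day", "epoch"])
        merged.insert(0, "subject_id", sid)
        epoch_frames.append(merged)
        daily = (unlock.groupby("day", as_index=False)
                 .agg(unlock_minutes=("unlock_minutes", "sum"),
                      coverage_hours=("coverage_hours", "first")))
        daily["day_valid"] = daily["coverage_hours"] >= cfg.min_coverage_hours
        mean = sensing.subject_mean_unlock(daily, min_days=cfg.min_days)
        rows.append({"subject_id": sid,
                     "n_valid_days": int(daily["day_valid"].sum()),
                     "mean_unlock_minutes": mean,
                     "included": mean is not None})
    io.write_table_tsv(pd.concat(epoch_frames, ignore_index=True),
                       out / f"{name}_epoch_features.tsv")
    summary = pd.DataFrame(rows)
    io.write_table_tsv(summary, out / f"{name}_mean_unlock.tsv")
    inc = summary[summary["included"]]
    print(f"{name}: {len(inc)}/{len(summary)} subjects pass the "
          f"{cfg.min_days}-day rule; mean daily unlock "
          f"{inc['mean_unlock_minutes'].mean():.1f} min")
print(f"feature tables under {out}")
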