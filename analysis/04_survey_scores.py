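"""Score the PHQ surveys: one pre-scan PHQ-8 plus weekly PHQ-4 EMAs per
subject, averaged across administrations, with Kroenke severity categories.

Writes results/surveys/.
"""

from studyconf import RESULTS

from phenoconn import io, surveys

out = RESULTS / "surveys"
out.mkdir(parents=True, exist_ok=True)

for name in ("cohort1", "cohort2"):
    resp = io.read_table_tsv(RESULTS / "data" / f"{name}_surveys.tsv")
    scores = surveys.score_survey_table(resp)
    io.write_table_tsv(scores, out / f"{name}_phq_scores.tsv")
    counts = scores["severity"].value_counts()
    print(f"{name}: mean PHQ-8 {scores['phq8'].mean():.2f}, "
          f"mean PHQ-2 {scores['phq2_mean'].mean():.2f}; "
          f"severity minimal/mild+ = {counts.get('minimal', 0)}/"
          f"{len(scores) - counts.get('minimal', 0)}")
print(f"survey scores under {out}")
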