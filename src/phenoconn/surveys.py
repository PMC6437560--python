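"""PHQ depression-survey scoring and EMA averaging.

PHQ-8 (8 items) is administered once pre-scan; PHQ-4 (4 items: two
depression items forming the PHQ-2 plus two anxiety items) arrives as a
weekly in-app EMA.  Items are ordinal 0-3 and instrument totals are plain
sums; repeated EMA administrations are averaged, and a single response is
sufficient for inclusion.  Severity categories for the PHQ-8 total follow
the cutpoint table in :data:`phenoconn.config.SEVERITY_CUTPOINTS`.
"""

from __future__ import annotations

import pandas as pd

from .config import SEVERITY_CUTPOINTS

N_ITEMS = {"PHQ8": 8, "PHQ4": 4}
PHQ2_ITEMS = (0, 1)  # depression items within the PHQ-4


class SurveyValidationError(ValueError):
    pass


def _check_items(items, instrument: str) -> list[int]:
    items = [int(v) for v in items]
    if len(items) != N_ITEMS[instrument]:
        raise SurveyValidationError(
            f"{instrument} requires {N_ITEMS[instrument]} items, got {len(items)}")
    for v in items:
        if not 0 <= v <= 3:
            raise SurveyValidationError(f"item score {v} outside 0-3")
    return items


def score_phq(items, instrument: str) -> int:
    """Sum of item scores (0-3 each)."""
    return sum(_check_items(items, instrument))


def phq2_from_phq4(items) -> int:
    """PHQ-2 = sum of the two depression items of a PHQ-4 response."""
    items = _check_items(items, "PHQ4")
    return sum(items[i] for i in PHQ2_ITEMS)


def severity_category(phq8_total: int) -> str:
    """Kroenke severity category for a PHQ-8 total (0-24)."""
    total = int(phq8_total)
    for name, (lo, hi) in SEVERITY_CUTPOINTS.items():
        if lo <= total <= hi:
            return name
    raise SurveyValidationError(f"PHQ-8 total {total} outside 0-24")


def ema_average(totals) -> float | None:
    """Mean instrument total across administrations; None (excluded) for an
    empty set."""
    totals = list(totals)
    if not totals:
        return None
    return float(sum(totals)) / len(totals)


def score_survey_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-subject score table from a long-format response table
    (subject_id, instrument, item_index, score, timestamp).

    Item-level missingness is rejected: each administration must carry a
    full item set.  Output columns: subject_id, phq8, phq4_mean, phq2_mean,
    severity (category of the PHQ-8 total; empty when no PHQ-8 exists).
    """
    rows = []
    for subject_id, grp in responses.groupby("subject_id", sort=True):
        phq8_totals, phq4_totals, phq2_totals = [], [], []
        for (instrument, _), adm in grp.groupby(["instrument", "timestamp"], sort=True):
            items = adm.sort_values("item_index")["score"].tolist()
            if instrument == "PHQ8":
                phq8_totals.append(score_phq(items, "PHQ8"))
            elif instrument == "PHQ4":
                phq4_totals.append(score_phq(items, "PHQ4"))
                phq2_totals.append(phq2_from_phq4(items))
            else:
                raise SurveyValidationError(f"unknown instrument {instrument!r}")
        phq8 = ema_average(phq8_totals)
        rows.append({
            "subject_id": subject_id,
            "phq8": phq8,
            "phq4_mean": ema_average(phq4_totals),
            "phq2_mean": ema_average(phq2_totals),
            "severity": severity_category(round(phq8)) if phq8 is not None else "",
        })
    return pd.DataFrame(rows, columns=["subject_id", "phq8", "phq4_mean",
                                       "phq2_mean", "severity"])
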