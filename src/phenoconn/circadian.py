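"""Circadian-similarity statistic: NaN-tolerant intra-class correlation.

A subject's day x epoch feature matrix (n_days x 3: day, evening, night)
is scored with a two-way, single-measure, *consistency* ICC with the three
epochs as targets and days as raters — how reproducible the within-day
profile is from day to day.  Means and sums ignore missing cells and the
error degrees of freedom are reduced by the number of missing cells, which
is the NaN-operator substitution of the standard balanced formulas.

The orientation (epochs as targets) is a package choice recorded in the
output metadata; ``transpose=True`` scores the other orientation for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ICC_FORM = "ICC(3,1) two-way mixed, single measure, consistency; targets=epochs, raters=days"


class InsufficientDataError(ValueError):
    pass


@dataclass
class IccResult:
    icc: float                  # NaN when undefined (degenerate variance)
    n_days_used: int
    n_missing_cells: int
    form: str = ICC_FORM

    @property
    def defined(self) -> bool:
        return np.isfinite(self.icc)


def nan_icc(matrix: np.ndarray, transpose: bool = False) -> IccResult:
    """NaN-tolerant two-way consistency ICC of an [n_days x 3] matrix.

    Requires at least 2 days with at least 2 observed epochs each.  Returns
    an undefined marker (NaN) when the between-target mean square is not
    estimable or total variance is degenerate.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InsufficientDataError("matrix must be 2-D [n_days x 3]")
    if not transpose and x.shape[1] != 3:
        raise InsufficientDataError("matrix must have exactly 3 epoch columns")
    if transpose:
        x = x.T
    obs = np.isfinite(x)
    full_rows = (obs.sum(axis=1) >= 2)
    if full_rows.sum() < 2:
        raise InsufficientDataError("need >= 2 days with >= 2 observed epochs")
    x = x[full_rows]
    obs = obs[full_rows]

    n_rows, n_cols = x.shape        # raters (days), targets (epochs)
    n = int(obs.sum())
    n_missing = n_rows * n_cols - n
    grand = np.nansum(x) / n
    col_counts = obs.sum(axis=0)
    row_counts = obs.sum(axis=1)
    col_means = np.nansum(x, axis=0) / col_counts
    row_means = np.nansum(x, axis=1) / row_counts

    ss_total = np.nansum((x - grand) ** 2)
    ss_cols = float((col_counts * (col_means - grand) ** 2).sum())   # targets
    ss_rows = float((row_counts * (row_means - grand) ** 2).sum())   # raters
    ss_err = max(ss_total - ss_cols - ss_rows, 0.0)

    df_cols = n_cols - 1
    df_rows = n_rows - 1
    df_err = (n - 1) - df_cols - df_rows
    if df_err <= 0 or df_cols <= 0:
        return IccResult(icc=np.nan, n_days_used=n_rows, n_missing_cells=n_missing)
    ms_cols = ss_cols / df_cols
    ms_err = ss_err / df_err
    k = n / n_cols                   # average raters per target
    denom = ms_cols + (k - 1) * ms_err
    if denom <= 0:
        return IccResult(icc=np.nan, n_days_used=n_rows, n_missing_cells=n_missing)
    icc = (ms_cols - ms_err) / denom
    return IccResult(icc=float(icc), n_days_used=n_rows, n_missing_cells=n_missing)


def circadian_similarity(epoch_table: pd.DataFrame, feature: str,
                         min_days: int = 20,
                         transpose: bool = False) -> IccResult | None:
    """Score one subject's DailyEpochTable; None means excluded.

    Only valid days (the 16-hour coverage rule, column ``day_valid``) enter
    the matrix; the subject is excluded below ``min_days`` valid days.
    """
    value_col = {"unlock": "unlock_minutes", "still": "still_minutes",
                 "locations": "unique_locations"}[feature]
    valid = epoch_table[epoch_table["day_valid"]]
    if len(valid) == 0:
        return None
    wide = valid.pivot_table(index="day", columns="epoch", values=value_col,
                             aggfunc="first")
    wide = wide.reindex(columns=["day", "evening", "night"])
    observed_days = wide.notna().any(axis=1).sum()
    if observed_days < min_days:
        return None
    try:
        return nan_icc(wide.to_numpy(), transpose=transpose)
    except InsufficientDataError:
        return None


def cohort_similarity_table(epoch_tables: dict[str, pd.DataFrame], feature: str,
                            min_days: int = 20) -> pd.DataFrame:
    """Per-subject similarity scores (NaN icc == undefined; missing row ==
    excluded by the min-days rule)."""
    rows = []
    for subject_id, table in epoch_tables.items():
        res = circadian_similarity(table, feature, min_days=min_days)
        if res is None:
            continue
        rows.append({"subject_id": subject_id, "feature": feature,
                     "icc": res.icc, "n_days_used": res.n_days_used,
                     "form": res.form})
    return pd.DataFrame(rows, columns=["subject_id", "feature", "icc",
                                       "n_days_used", "form"])
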