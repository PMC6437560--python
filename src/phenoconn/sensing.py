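"""Daily and epoch-level features from raw phone event streams.

Turns an event stream (unlock sessions, still intervals, location
observations, heartbeats) into:

* per-day unlock minutes with a 16-hour quality-coverage validity rule,
* a day x epoch feature table (unlock minutes, still minutes, unique
  100 m location cells) over the fixed epochs 9-18 (day), 18-24 (evening),
  0-9 (night), local naive clock,
* duty-cycle coverage upscaling (observed minutes / coverage fraction),
* the 20-valid-day subject-mean inclusion rule.

Interval events crossing midnight are split at the boundary so epoch and
daily totals are conserved.  "Quality coverage hours" counts the distinct
clock hours of a day touched by any event or heartbeat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthgen import EPOCHS, EPOCH_BOUNDS_MIN

LOCATION_CELL_M = 100.0
_M_PER_DEG_LAT = 110540.0
_M_PER_DEG_LON = 111320.0


class InputIntegrityError(ValueError):
    pass


def _prepare(events: pd.DataFrame) -> pd.DataFrame:
    if len(events) == 0:
        raise InputIntegrityError("empty event stream")
    ev = events.copy()
    ev["start"] = pd.to_datetime(ev["start"])
    ev["end"] = pd.to_datetime(ev["end"])
    return ev.sort_values(["start", "end"], kind="stable").reset_index(drop=True)


def _check_no_overlap(sessions: pd.DataFrame) -> None:
    s = sessions.sort_values("start", kind="stable").reset_index()
    late = s["start"].iloc[1:].to_numpy()
    early = s["end"].iloc[:-1].to_numpy()
    bad = np.nonzero(late < early)[0]
    if len(bad):
        i = int(bad[0])
        raise InputIntegrityError(
            "overlapping unlock sessions: "
            f"({s['start'].iloc[i]} - {s['end'].iloc[i]}) and "
            f"({s['start'].iloc[i + 1]} - {s['end'].iloc[i + 1]})")


def split_at_midnight(start: pd.Timestamp, end: pd.Timestamp):
    """Yield (day, piece_start, piece_end) with pieces clipped to calendar
    days; conserves total duration."""
    cur = start
    while cur < end:
        day = cur.normalize()
        nxt = day + pd.Timedelta(days=1)
        piece_end = min(end, nxt)
        yield day, cur, piece_end
        cur = piece_end


def coverage_hours(events: pd.DataFrame) -> pd.Series:
    """Distinct clock hours per calendar day touched by any event (point
    events such as heartbeats and location observations count)."""
    rows: dict[pd.Timestamp, set[int]] = {}
    for _, ev in events.iterrows():
        start = ev["start"]
        end = ev["end"] if pd.notna(ev["end"]) else start
        if end <= start:  # point event
            rows.setdefault(start.normalize(), set()).add(start.hour)
            continue
        for day, s, e in split_at_midnight(start, end):
            # [s, e) touches hours s.hour .. hour of the last instant before e
            last = (e - pd.Timedelta(microseconds=1)).hour
            rows.setdefault(day, set()).update(range(s.hour, last + 1))
    return pd.Series({d: float(len(h)) for d, h in sorted(rows.items())},
                     name="coverage_hours")


def daily_unlock_duration(events: pd.DataFrame,
                          min_coverage_hours: float = 16.0) -> pd.DataFrame:
    """Per-day unlock minutes plus quality flags.

    Sessions crossing midnight are split at the boundary.  Days whose
    quality coverage is below ``min_coverage_hours`` are flagged invalid.
    Overlapping unlock sessions are an input-integrity error.
    """
    ev = _prepare(events)
    sessions = ev[ev["event_type"] == "unlock_session"]
    if len(sessions):
        _check_no_overlap(sessions)
    per_day: dict[pd.Timestamp, float] = {}
    for _, s in sessions.iterrows():
        for day, ps, pe in split_at_midnight(s["start"], s["end"]):
            per_day[day] = per_day.get(day, 0.0) + (pe - ps).total_seconds() / 60.0
    cov = coverage_hours(ev)
    days = sorted(set(per_day) | set(cov.index))
    out = pd.DataFrame({
        "day": [d.date().isoformat() for d in days],
        "unlock_minutes": [per_day.get(d, 0.0) for d in days],
        "coverage_hours": [float(cov.get(d, 0.0)) for d in days],
    })
    out["day_valid"] = out["coverage_hours"] >= min_coverage_hours
    return out


def subject_mean_unlock(daily: pd.DataFrame, min_days: int = 20) -> float | None:
    """Mean daily unlock minutes over valid days, or None (excluded) when
    fewer than ``min_days`` valid days exist."""
    valid = daily[daily["day_valid"]]
    if len(valid) < min_days:
        return None
    return float(valid["unlock_minutes"].mean())


def _interval_epoch_minutes(start: pd.Timestamp, end: pd.Timestamp):
    """Yield (day, epoch, minutes) overlaps of [start, end) with every
    (day, epoch) window it touches."""
    for day, s, e in split_at_midnight(start, end):
        s_min = (s - day).total_seconds() / 60.0
        e_min = (e - day).total_seconds() / 60.0
        for epoch in EPOCHS:
            lo, hi = EPOCH_BOUNDS_MIN[epoch]
            ov = min(e_min, hi) - max(s_min, lo)
            if ov > 0:
                yield day, epoch, ov


def location_cell(lat: float, lon: float) -> tuple[int, int]:
    """Snap coordinates to a square ~100 m grid (local equirectangular)."""
    x = lon * _M_PER_DEG_LON * np.cos(np.radians(lat))
    y = lat * _M_PER_DEG_LAT
    return int(np.floor(x / LOCATION_CELL_M)), int(np.floor(y / LOCATION_CELL_M))


def epoch_partition(events: pd.DataFrame, feature: str,
                    min_coverage_hours: float = 16.0) -> pd.DataFrame:
    """Day x epoch table for one feature in {"unlock", "still", "locations"}.

    Interval features are apportioned to epochs by overlap; ``locations``
    counts distinct 100 m cells per (day, epoch).
    """
    ev = _prepare(events)
    cov = coverage_hours(ev)
    rows: dict[tuple[pd.Timestamp, str], float] = {}
    if feature in ("unlock", "still"):
        etype = "unlock_session" if feature == "unlock" else "still_interval"
        sub = ev[ev["event_type"] == etype]
        for _, r in sub.iterrows():
            for day, epoch, minutes in _interval_epoch_minutes(r["start"], r["end"]):
                rows[(day, epoch)] = rows.get((day, epoch), 0.0) + minutes
        colname = f"{feature}_minutes"
    elif feature == "locations":
        sub = ev[ev["event_type"] == "location_obs"]
        cells: dict[tuple[pd.Timestamp, str], set] = {}
        for _, r in sub.iterrows():
            day = r["start"].normalize()
            m = (r["start"] - day).total_seconds() / 60.0
            for epoch in EPOCHS:
                lo, hi = EPOCH_BOUNDS_MIN[epoch]
                if lo <= m < hi:
                    cells.setdefault((day, epoch), set()).add(
                        location_cell(r["latitude"], r["longitude"]))
        rows = {k: float(len(v)) for k, v in cells.items()}
        colname = "unique_locations"
    else:
        raise ValueError(f"unknown feature {feature!r}")

    days = sorted(set(d for d, _ in rows) | set(cov.index))
    table = []
    for day in days:
        for epoch in EPOCHS:
            table.append({
                "day": day.date().isoformat(),
                "epoch": epoch,
                colname: rows.get((day, epoch), 0.0),
                "coverage_hours": float(cov.get(day, 0.0)),
            })
    out = pd.DataFrame(table)
    out["day_valid"] = out["coverage_hours"] >= min_coverage_hours
    return out


def coverage_upscale(observed: pd.DataFrame, schedule: pd.DataFrame,
                     value_col: str) -> pd.DataFrame:
    """Estimate true epoch minutes from duty-cycled observations:
    estimate = observed / realized coverage fraction.  Continuous schedules
    (coverage 1.0) pass through unchanged.  Zero coverage with a nonzero
    observation is an integrity error."""
    sched = schedule[["day", "epoch", "coverage"]]
    merged = observed.merge(sched, on=["day", "epoch"], how="left")
    merged["coverage"] = merged["coverage"].fillna(1.0)
    bad = (merged["coverage"] == 0) & (merged[value_col] > 0)
    if bad.any():
        row = merged[bad].iloc[0]
        raise InputIntegrityError(
            f"nonzero observation with zero coverage on {row['day']} {row['epoch']}")
    est = merged[value_col] / merged["coverage"].replace(0.0, 1.0)
    out = merged.drop(columns=["coverage"]).copy()
    out[value_col] = est
    return out
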