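"""Adherence and depression endpoint derivation.

Raw trial records (dispensing logs, MEMS cap-opening event streams, QIDS-SR
scores) are reduced here to the analysis endpoints:

* primary — % adherence by pill count:
  ``100 * (prescribed - remaining) / days between dispensing and return``;
* secondary — % of doses taken on schedule by MEMS, where "on schedule"
  means within +/-6 h of the participant's expected dosing time, estimated
  by fitting a line to their daily dosing clock-times;
* exploratory — QIDS-SR remission (score <= 5 by default) and response
  (>= 50% reduction from baseline);
* the intention-to-treat rule: participants who withdraw are scored
  non-adherent (both endpoints 0) for every remaining scheduled visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DispensingRecord",
    "MemsEventLog",
    "SCHEDULED_VISIT_WEEKS",
    "pill_count_pct",
    "mems_on_schedule_pct",
    "qids_remission",
    "qids_response",
    "itt_impute",
    "derive_adherence",
]

SCHEDULED_VISIT_WEEKS = (2, 4, 8)

# Dispensing intervals backing each scheduled visit: week 0->2, 2->4, 4->8.
VISIT_INTERVAL_DAYS = {2: (0, 14), 4: (14, 28), 8: (28, 56)}

# Floating-point guard on the +/-6 h window so exactly-boundary residuals
# (e.g. a dose precisely 6 h off trend) count as on schedule.
_WINDOW_TOL_H = 1e-9


@dataclass
class DispensingRecord:
    participant_id: str
    n_prescribed: int
    n_remaining: int
    dispense_date: date
    return_date: date

    def __post_init__(self) -> None:
        if self.n_remaining > self.n_prescribed:
            raise ValueError("more pills remaining than prescribed")
        if self.return_date <= self.dispense_date:
            raise ValueError("return date must follow dispensing date")


@dataclass
class MemsEventLog:
    participant_id: str
    open_timestamps: Sequence[datetime]
    schedule_start: datetime
    schedule_end: datetime

    def __post_init__(self) -> None:
        ts = pd.to_datetime(list(self.open_timestamps))
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be sorted ascending")
        self.open_timestamps = ts
        if len(ts) and (ts.min() < pd.Timestamp(self.schedule_start)
                        or ts.max() > pd.Timestamp(self.schedule_end)):
            raise ValueError("event outside the dosing schedule interval")


def pill_count_pct(rec: DispensingRecord, clamp: bool = False) -> float:
    """% adherence by pill count over the dispensing interval.

    One pill is prescribed per day, so the denominator is the day span
    between dispensing and return.  Late returns can push the value past
    100%; values are reported as computed unless ``clamp`` is set.
    """
    days = (rec.return_date - rec.dispense_date).days
    if days <= 0:
        raise ValueError("dispensing interval must span at least one day")
    pct = 100.0 * (rec.n_prescribed - rec.n_remaining) / days
    return min(pct, 100.0) if clamp else pct


def _clock_hours_unwrapped(ts: pd.DatetimeIndex) -> np.ndarray:
    """Hours since midnight, unwrapped around the median so habitual dosing
    near midnight does not straddle the 0/24 discontinuity."""
    h = (ts - ts.normalize()) / pd.Timedelta(hours=1)
    h = np.asarray(h, dtype=float)
    med = np.median(h)
    return med + ((h - med + 12.0) % 24.0) - 12.0


def mems_on_schedule_pct(log: MemsEventLog, window_hours: float = 6.0) -> float:
    """% of scheduled days with a cap opening near the expected dosing time.

    The expected time per day comes from an ordinary least-squares line of
    dosing clock-time on day index (first opening per day; extra openings are
    treated as curiosity openings and ignored).  A day is on schedule if its
    opening lies within ``window_hours`` (inclusive) of the line; days
    without an opening count as missed.
    """
    start = pd.Timestamp(log.schedule_start)
    n_days = (pd.Timestamp(log.schedule_end).normalize()
              - start.normalize()).days
    if n_days <= 0:
        raise ValueError("schedule interval must cover at least one day")
    ts = pd.DatetimeIndex(log.open_timestamps)
    if len(ts) < 2:
        warnings.warn("fewer than 2 MEMS events; cannot fit a dosing trend, "
                      "returning 0%", stacklevel=2)
        return 0.0
    day_idx = np.asarray((ts.normalize() - start.normalize()).days)
    hours = _clock_hours_unwrapped(ts)
    # first opening per day
    first = pd.Series(hours, index=day_idx).groupby(level=0).first()
    days = first.index.to_numpy(dtype=float)
    times = first.to_numpy()
    if len(days) >= 2:
        slope, intercept = np.polyfit(days, times, 1)
    else:
        slope, intercept = 0.0, float(times[0])
    resid = np.abs(times - (intercept + slope * days))
    on_schedule = int(np.sum(resid <= window_hours + _WINDOW_TOL_H))
    return 100.0 * on_schedule / n_days


def qids_remission(score: float, threshold: float = 5.0) -> bool:
    """QIDS-SR remission: total score at or below the threshold."""
    _check_qids(score)
    return score <= threshold


def qids_response(score: float, baseline: float) -> bool:
    """QIDS-SR response: at least a 50% reduction from baseline."""
    _check_qids(score)
    _check_qids(baseline)
    return score <= 0.5 * baseline


def _check_qids(score: float) -> None:
    if not 0 <= score <= 27:
        raise ValueError(f"QIDS-SR score {score} outside [0, 27]")


def itt_impute(records: pd.DataFrame,
               withdrawal_week: float | None,
               visit_weeks: Iterable[int] = SCHEDULED_VISIT_WEEKS,
               ) -> pd.DataFrame:
    """Apply the intention-to-treat non-adherence rule to one participant.

    ``records`` holds that participant's observed adherence rows (columns
    ``visit_week``, ``pill_count_pct``, ``mems_pct`` and any identifiers).
    Visits at or after the withdrawal week get both endpoints set to 0 with
    the ``imputed`` flag raised, and a row is guaranteed for every scheduled
    visit.
    """
    records = records.copy()
    if "imputed" not in records.columns:
        records["imputed"] = False
    carry = {c: records[c].iloc[0] for c in records.columns
             if c not in ("visit_week", "pill_count_pct", "mems_pct",
                          "imputed")} if len(records) else {}
    rows = []
    for week in visit_weeks:
        match = records[records["visit_week"] == week]
        withdrawn = withdrawal_week is not None and week >= withdrawal_week
        if withdrawn or match.empty:
            rows.append({**carry, "visit_week": week,
                         "pill_count_pct": 0.0, "mems_pct": 0.0,
                         "imputed": True})
        else:
            rows.append(match.iloc[0].to_dict())
    return pd.DataFrame(rows, columns=records.columns
                        if len(records) else None)


def derive_adherence(visits: pd.DataFrame, mems_events: pd.DataFrame,
                     window_hours: float = 6.0,
                     visit_weeks: Iterable[int] = SCHEDULED_VISIT_WEEKS,
                     ) -> pd.DataFrame:
    """Derive the long-format adherence table for a whole trial.

    ``visits`` is the per-visit table (participant_id, arm, visit_week,
    n_prescribed, n_remaining, dispense_date, return_date, withdrawal_week,
    ...); ``mems_events`` has one row per cap opening (participant_id,
    timestamp).  Returns one row per participant x scheduled visit with
    pill_count_pct, mems_pct and the ITT imputation applied.
    """
    visits = visits.copy()
    for col in ("dispense_date", "return_date"):
        visits[col] = pd.to_datetime(visits[col])
    mems_events = mems_events.copy()
    mems_events["timestamp"] = pd.to_datetime(mems_events["timestamp"])

    out = []
    for pid, grp in visits.groupby("participant_id", sort=True):
        ww = grp["withdrawal_week"].iloc[0]
        ww = None if pd.isna(ww) else float(ww)
        arm = grp["arm"].iloc[0]
        ev = mems_events.loc[mems_events["participant_id"] == pid,
                             "timestamp"].sort_values()
        adherence_rows = []
        for _, row in grp.dropna(subset=["n_prescribed"]).iterrows():
            week = int(row["visit_week"])
            if week not in visit_weeks:
                continue
            rec = DispensingRecord(pid, int(row["n_prescribed"]),
                                   int(row["n_remaining"]),
                                   row["dispense_date"].date(),
                                   row["return_date"].date())
            window = ev[(ev >= row["dispense_date"])
                        & (ev < row["return_date"])]
            if len(window) >= 2:
                mlog = MemsEventLog(pid, list(window),
                                    row["dispense_date"].to_pydatetime(),
                                    row["return_date"].to_pydatetime())
                mems = mems_on_schedule_pct(mlog, window_hours)
            else:
                mems = 0.0
            adherence_rows.append({
                "participant_id": pid, "arm": arm, "visit_week": week,
                "pill_count_pct": pill_count_pct(rec), "mems_pct": mems,
                "imputed": False})
        part = pd.DataFrame(adherence_rows, columns=[
            "participant_id", "arm", "visit_week", "pill_count_pct",
            "mems_pct", "imputed"])
        if part.empty:
            # no observed visits at all: every scheduled visit is imputed
            part = pd.DataFrame([{"participant_id": pid, "arm": arm,
                                  "visit_week": w, "pill_count_pct": 0.0,
                                  "mems_pct": 0.0, "imputed": True}
                                 for w in visit_weeks])
            out.append(part)
            continue
        out.append(itt_impute(part, ww, visit_weeks))
    return pd.concat(out, ignore_index=True)
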