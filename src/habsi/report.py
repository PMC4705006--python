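"""Monthly surveillance report tables.

One row per calendar month of the reporting period: episode counts,
incidence per 1000 patient-days, the classification mix, and the
confirmation-delay mean/SD.  Events are assigned to a month by onset for
counting and incidence, and by confirmation date for the delay columns —
each statistic follows its own definition.  Row sums equal the pipeline
event totals: no event is lost or double-counted across months.
"""

from __future__ import annotations

import calendar
from datetime import date

import pandas as pd

from .linkage import patient_days
from .metrics import delay_stats, incidence
from .records import Classification, Episode, HabsiEvent

__all__ = ["monthly_report", "months_in"]


def months_in(period: tuple[date, date]) -> list[str]:
    """Calendar months ('YYYY-MM') intersecting an inclusive date interval."""
    first, last = period
    if last < first:
        return []
    out = []
    y, m = first.year, first.month
    while (y, m) <= (last.year, last.month):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def _month_bounds(month: str) -> tuple[date, date]:
    y, m = int(month[:4]), int(month[5:])
    return date(y, m, 1), date(y, m, calendar.monthrange(y, m)[1])


def monthly_report(
    events: list[HabsiEvent],
    episodes: list[Episode],
    period: tuple[date, date],
) -> pd.DataFrame:
    """Build the per-month surveillance table for ``period``."""
    months = months_in(period)
    delays = delay_stats(events)
    delay_by_month = {
        row["month"]: row for _, row in delays.iterrows() if row["month"] != "period"
    }
    class_values = [c.value for c in Classification]

    rows = []
    for month in months:
        lo, hi = _month_bounds(month)
        lo, hi = max(lo, period[0]), min(hi, period[1])
        in_month = [e for e in events if lo <= e.onset_ts.date() <= hi]
        pdays = patient_days(episodes, (lo, hi))
        row = {
            "month": month,
            "events": len(in_month),
            "patient_days": pdays,
            "rate_per_1000_patient_days": incidence(len(in_month), pdays) if pdays else None,
        }
        for cv in class_values:
            row[cv] = sum(1 for e in in_month if e.classification.value == cv)
        d = delay_by_month.get(month)
        row["delay_mean_days"] = None if d is None else float(d["mean"])
        row["delay_sd_days"] = None if d is None else float(d["sd"])
        row["delay_n"] = 0 if d is None else int(d["n"])
        rows.append(row)
    columns = [
        "month", "events", "patient_days", "rate_per_1000_patient_days",
        *class_values, "delay_mean_days", "delay_sd_days", "delay_n",
    ]
    return pd.DataFrame(rows, columns=columns)
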