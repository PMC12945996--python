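"""Time-to-onset (TTO) analysis of adverse-event reports.

TTO is the interval in days from therapy initiation to adverse-event onset.
Spontaneous reports carry famously unreliable dates, so a report enters the
TTO analysis only when both dates are complete (day+month+year) and the
interval is non-negative; every other report is assigned an explicit
exclusion status rather than silently dropped.  Included intervals are
summarized in the conventional 30-day bins (with a wide 181–360 bin and an
open >360 tail) and by linear-interpolation quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _dates
from .ingest import CleanCases

__all__ = ["TTO_BIN_LABELS", "TTORecord", "TTOSummary",
           "compute_tto", "compute_tto_frame", "summarize_tto"]

# upper-inclusive integer-day bins: 0–30 means 0 <= t <= 30
TTO_BIN_LABELS = ("0-30", "31-60", "61-90", "91-120",
                  "121-150", "151-180", "181-360", ">360")
_BIN_UPPER = (30, 60, 90, 120, 150, 180, 360)

STATUS_INCLUDED = "included"
STATUS_NEGATIVE = "excluded_negative"
STATUS_INCOMPLETE = "excluded_incomplete_date"
STATUS_MISSING = "excluded_missing"


@dataclass(frozen=True)
class TTORecord:
    """Per-report onset interval with its inclusion status."""

    case_id: str
    start_date: str
    event_date: str
    status: str
    tto_days: int | None = None


@dataclass
class TTOSummary:
    """Binned counts and quartile statistics over included records."""

    n_included: int
    bin_counts: dict
    bin_percent: dict
    mean: float
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Group": [f"{lbl} days" if not lbl.startswith(">") else f"{lbl} days"
                      for lbl in TTO_BIN_LABELS],
            "n": [self.bin_counts[lbl] for lbl in TTO_BIN_LABELS],
            "Percent": [self.bin_percent[lbl] for lbl in TTO_BIN_LABELS],
        })


def compute_tto(start_date, event_date, case_id: str = "") -> TTORecord:
    """Classify one report and compute its onset interval.

    Either date absent -> ``excluded_missing``; present but partial or not a
    real calendar date -> ``excluded_incomplete_date``; negative interval ->
    ``excluded_negative``; otherwise included with the whole-day interval.
    """
    s = _dates.clean_date_str(start_date)
    e = _dates.clean_date_str(event_date)
    if not s or not e:
        return TTORecord(case_id, s, e, STATUS_MISSING)
    d0, d1 = _dates.to_date(s), _dates.to_date(e)
    if d0 is None or d1 is None:
        return TTORecord(case_id, s, e, STATUS_INCOMPLETE)
    days = (d1 - d0).days
    if days < 0:
        return TTORecord(case_id, s, e, STATUS_NEGATIVE)
    return TTORecord(case_id, s, e, STATUS_INCLUDED, tto_days=days)


def compute_tto_frame(clean: CleanCases, target_only: bool = True) -> pd.DataFrame:
    """One TTO record per clean case (therapy start -> event date).

    ``target_only`` restricts to cases whose matched target drug passed the
    role filter, the reports the onset question is actually about.
    """
    cases = clean.cases
    if target_only:
        cases = cases[cases["case_class"] == "target"]
    recs = [compute_tto(s, e, case_id=cid)
            for cid, s, e in zip(cases["case_id"], cases["start_dt"],
                                 cases["event_dt"])]
    return pd.DataFrame(
        {"case_id": [r.case_id for r in recs],
         "start_date": [r.start_date for r in recs],
         "event_date": [r.event_date for r in recs],
         "status": [r.status for r in recs],
         "tto_days": [r.tto_days for r in recs]})


def _bin_label(t: int) -> str:
    for lbl, hi in zip(TTO_BIN_LABELS, _BIN_UPPER):
        if t <= hi:
            return lbl
    return TTO_BIN_LABELS[-1]


def summarize_tto(tto_days) -> TTOSummary:
    """Summarize included onset intervals.

    Accepts a sequence of non-negative whole-day intervals.  Quartiles use
    linear interpolation between order statistics; percentages are rounded
    to 2 dp.  An empty input yields n=0 with NaN quartiles.
    """
    vals = np.asarray([t for t in tto_days if t is not None and not np.isnan(t)],
                      dtype=float)
    if vals.size and vals.min() < 0:
        raise ValueError("negative interval reached summarize_tto; "
                         "exclusions must be applied first")
    counts = {lbl: 0 for lbl in TTO_BIN_LABELS}
    for t in vals:
        counts[_bin_label(int(t))] += 1
    n = int(vals.size)
    if n == 0:
        pct = {lbl: float("nan") for lbl in TTO_BIN_LABELS}
        return TTOSummary(0, counts, pct, *(float("nan"),) * 4)
    pct = {lbl: round(100.0 * counts[lbl] / n, 2) for lbl in TTO_BIN_LABELS}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return TTOSummary(n_included=n, bin_counts=counts, bin_percent=pct,
                      mean=float(vals.mean()), median=float(med),
                      q1=float(q1), q3=float(q3))
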