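"""Partial-date handling for FAERS-style ``YYYYMMDD`` fields.

FAERS emits calendar fields as integers at whatever precision the reporter
supplied: ``YYYYMMDD``, ``YYYYMM`` or ``YYYY``.  Deduplication needs a total
order over these (missing trailing components sort earliest); time-to-onset
needs strict completeness (a partial date is an exclusion, not a guess).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

__all__ = [
    "clean_date_str",
    "date_sort_key",
    "to_date",
    "is_complete",
]


def clean_date_str(value) -> str:
    """Normalize a raw date field to a digit string ('' when absent)."""
    if value is None:
        return ""
    if isinstance(value, float) and np.isnan(value):
        return ""
    s = str(value).strip()
    if s.lower() in {"", "nan", "none", "na"}:
        return ""
    if s.endswith(".0"):  # ints round-tripped through float columns
        s = s[:-2]
    return s if s.isdigit() else ""


def date_sort_key(value) -> str:
    """Zero-padded 8-char key; missing components sort as earliest."""
    s = clean_date_str(value)
    return (s + "00000000")[:8] if s else "00000000"


def is_complete(value) -> bool:
    """True iff the field has day+month+year and is a real calendar date."""
    return to_date(value) is not None


def to_date(value):
    """Parse a complete ``YYYYMMDD`` field; return ``None`` otherwise."""
    s = clean_date_str(value)
    if len(s) != 8:
        return None
    try:
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def days_between(start, event) -> float:
    """event − start in whole days; NaN when either date is incomplete."""
    d0, d1 = to_date(start), to_date(event)
    if d0 is None or d1 is None:
        return float("nan")
    return float((d1 - d0).days)


def series_sort_key(s: pd.Series) -> pd.Series:
    """Vectorized :func:`date_sort_key`."""
    return s.map(date_sort_key)
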