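"""Precomputed calendar lookup tables for fast day-grid arithmetic.

All person-time bookkeeping in this package happens on proleptic-Gregorian
day ordinals (``datetime.date.toordinal``).  The tables below cover every
day from 1980-01-01 to 2035-12-31, which comfortably contains any study
window bounded by the 2001-2014 study period plus the 6-19 year age range.
Indexing is ``array[ordinal - CAL_START]``.
"""

from __future__ import annotations

from datetime import date

import numpy as np

CAL_START = date(1980, 1, 1).toordinal()
CAL_END = date(2036, 1, 1).toordinal()  # exclusive

_EPOCH = date(1970, 1, 1).toordinal()


def _build_tables():
    days = np.arange(CAL_START, CAL_END, dtype=np.int64)
    dt = (days - _EPOCH).astype("datetime64[D]")
    months64 = dt.astype("datetime64[M]")
    year = (months64.astype(np.int64) // 12 + 1970).astype(np.int16)
    month = (months64.astype(np.int64) % 12 + 1).astype(np.int8)
    dom = ((dt - months64).astype(np.int64) + 1).astype(np.int8)
    return year, month, dom


YEAR, MONTH, DOM = _build_tables()
#: calendar quarter 1-4 (Jan-Mar = 1, ..., Oct-Dec = 4)
SEASON = ((MONTH - 1) // 3 + 1).astype(np.int8)
#: months elapsed since Jan 1980 (0-based)
MONTH_INDEX = ((YEAR.astype(np.int32) - 1980) * 12 + MONTH - 1).astype(np.int32)
#: ordinal of the first day of month index m (for vectorised y/m/d -> ordinal)
ORD_OF_MONTH = np.flatnonzero(DOM == 1).astype(np.int64) + CAL_START


def span(start_ord: int, end_ord: int) -> slice:
    """Table slice for the inclusive day range [start_ord, end_ord]."""
    return slice(start_ord - CAL_START, end_ord + 1 - CAL_START)


def ord_ymd(year, month, day):
    """Vectorised ordinal of (year, month, day); day must exist in month."""
    y = np.asarray(year, dtype=np.int64)
    m = np.asarray(month, dtype=np.int64)
    d = np.asarray(day, dtype=np.int64)
    return ORD_OF_MONTH[(y - 1980) * 12 + (m - 1)] + (d - 1)


def anniversary(dob: date, years: int) -> int:
    """Ordinal of the ``years``-th birthday.

    A Feb-29 birth date rolls forward to Mar 1 in non-leap years, which is
    consistent with counting a month as completed only once the day-of-month
    has been reached.
    """
    try:
        return date(dob.year + years, dob.month, dob.day).toordinal()
    except ValueError:
        return date(dob.year + years, 3, 1).toordinal()


def age_months_grid(start_ord: int, end_ord: int, dob: date) -> np.ndarray:
    """Completed months of age for every day in [start_ord, end_ord]."""
    sl = span(start_ord, end_ord)
    dob_mi = (dob.year - 1980) * 12 + dob.month - 1
    return MONTH_INDEX[sl] - dob_mi - (DOM[sl] < dob.day)


def season_grid(start_ord: int, end_ord: int) -> np.ndarray:
    """Calendar quarter (1-4) for every day in [start_ord, end_ord]."""
    return SEASON[span(start_ord, end_ord)]
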