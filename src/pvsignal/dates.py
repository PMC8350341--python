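"""Partial calendar dates as they occur in spontaneous reporting systems.

JADER stores day-resolution dates, but many records carry only a year or a
year-month. A :class:`PartialDate` keeps whatever precision the source had;
analyses that need exact day arithmetic (time-to-onset) ask for
:meth:`PartialDate.is_complete` and convert the rest to missing.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_DATE_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")

YEAR_MIN, YEAR_MAX = 1990, 2100


@dataclass(frozen=True, order=True)
class PartialDate:
    """A date known to year, year-month, or full-day precision.

    Invariants: ``day is not None`` implies ``month is not None``; a complete
    (year, month, day) triple is a valid calendar date.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside {YEAR_MIN}-{YEAR_MAX}")
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month {self.month} out of range")
        if self.day is not None:
            # raises ValueError for impossible calendar dates (e.g. Feb 30)
            _dt.date(self.year, self.month, self.day)

    @property
    def is_complete(self) -> bool:
        return self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"{self} is not a complete date")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: object) -> PartialDate | None:
    """Parse ``YYYYMMDD`` / ``YYYYMM`` / ``YYYY`` strings; None if unparseable.

    Unparseable or impossible dates map to None (field missing, row retained).
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if not s or s.lower() in ("nan", "none"):
        return None
    if s.endswith(".0"):  # pandas float-read artefact
        s = s[:-2]
    m = _DATE_RE.match(s)
    if m is None:
        return None
    y, mo, d = m.group(1), m.group(2), m.group(3)
    try:
        return PartialDate(int(y), int(mo) if mo else None, int(d) if d else None)
    except ValueError:
        return None


def complete_dates(series: pd.Series) -> pd.Series:
    """Vectorised conversion of raw date strings to Timestamps.

    Only 8-digit, calendar-valid values convert; everything else is NaT.
    """
    s = series.astype("string").str.strip()
    s = s.where(s.str.fullmatch(r"\d{8}", na=False))
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")
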