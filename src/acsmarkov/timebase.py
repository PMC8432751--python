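"""Study calendar: all dates are integer day offsets from a fixed origin.

The study window opens 2015-04-01 (day 0) and closes for admissions
2018-08-31 (day 1248); mortality follow-up requires admission on or before
2018-01-01 (day 1006) so that 12 months of vital-statistics data exist.
Working in integer offsets keeps every table plain-text friendly and makes
window arithmetic exact.
"""

from __future__ import annotations

from datetime import date, timedelta

STUDY_ORIGIN = date(2015, 4, 1)

#: Last admission day of the study window (2018-08-31).
WINDOW_END_DAY = (date(2018, 8, 31) - STUDY_ORIGIN).days

#: Last admission day allowing 12 months of mortality follow-up (2018-01-01).
MORTALITY_CUTOFF_DAY = (date(2018, 1, 1) - STUDY_ORIGIN).days


def day_to_date(day: int) -> date:
    return STUDY_ORIGIN + timedelta(days=int(day))


def admission_quarter(day: int) -> str:
    """Calendar quarter label, e.g. ``'2015Q2'``, for a day offset."""
    d = day_to_date(day)
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"
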