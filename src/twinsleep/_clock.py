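"""Clock-time handling on a continuous minutes-from-noon axis.

Adolescent sleep onset spans midnight (roughly 19:30 one evening to 01:30 the
next morning), so naive clock arithmetic on hours-since-midnight breaks: 01:11
would sort before 21:51.  All internal times are therefore minutes measured
from 12:00 noon of the evening the night belongs to, so 21:51 -> 591 and
01:11 (next day) -> 786, and means, differences and midpoints are ordinary
arithmetic.
"""

from __future__ import annotations

import math

MINUTES_PER_DAY = 1440


def from_clock(hhmm: str) -> float:
    """Parse "hh:mm" to minutes from noon ("21:51" -> 591, "06:46" -> 1126).

    Times at or after 12:00 are read as the evening of the night; times
    before 12:00 as the following morning.
    """
    h, m = hhmm.split(":")
    minutes = int(h) * 60 + float(m)
    return (minutes - 720.0) % MINUTES_PER_DAY


def to_clock(minutes: float) -> str:
    """Format minutes-from-noon back to wall-clock "hh:mm" (rounded)."""
    if not math.isfinite(minutes):
        return ""
    wall = (minutes + 720.0) % MINUTES_PER_DAY
    total = int(round(wall))
    if total == MINUTES_PER_DAY:
        total = 0
    return f"{total // 60:02d}:{total % 60:02d}"
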