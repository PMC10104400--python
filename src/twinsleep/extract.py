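"""Nightly sleep measures from epoch-level arm-angle data plus a sleep diary.

The detection rule is the standard wrist-actigraphy heuristic: sustained
inactivity is a run of 5-second epochs whose arm angle changes by no more
than five degrees from one epoch to the next, lasting at least five minutes.
Runs intersected with the self-reported (diary) sleep window are classified
as sleep periods; the night's onset is the start of the first such period,
wake is the end of the last, duration is the summed period lengths, and the
midpoint is halfway between onset and wake.  The diary's morning question
("Refreshed" vs "Tired") is coded 1/0 as restorative sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EPOCH_MINUTES, AngleSeries

__all__ = [
    "NightSummary",
    "detect_inactivity_periods",
    "classify_sleep_periods",
    "summarize_night",
    "extract_night",
]

ANGLE_THRESHOLD_DEG = 5.0
MIN_RUN_MINUTES = 5.0


@dataclass(frozen=True)
class NightSummary:
    """One night's extracted sleep measures (minutes from noon)."""

    onset: float
    wake: float
    duration: float
    midpoint: float
    restorative: float  # 1.0 refreshed, 0.0 tired, NaN missing
    night_type: str = ""

    def __post_init__(self):
        if not self.onset < self.wake:
            raise ValueError("onset must precede wake on the continuous axis")
        if self.duration > self.wake - self.onset + 1e-9:
            raise ValueError("duration cannot exceed wake - onset")


def detect_inactivity_periods(
    series: AngleSeries,
    angle_threshold: float = ANGLE_THRESHOLD_DEG,
    min_duration: float = MIN_RUN_MINUTES,
) -> list[tuple[float, float]]:
    """Maximal sustained-inactivity intervals in an angle trace.

    An epoch continues a run when its angle differs from the previous epoch's
    by at most ``angle_threshold`` degrees; runs shorter than ``min_duration``
    minutes are discarded.  Returns disjoint, sorted (start, end) intervals
    in minutes, where an n-epoch run spans n epoch lengths.
    """
    t = series.times
    if len(t) < 60:
        raise ValueError("need at least 60 epochs (5 minutes) of data")
    steps = np.diff(t)
    if not np.allclose(steps, EPOCH_MINUTES, atol=1e-9):
        raise ValueError("irregular epoch spacing; expected constant 5 s epochs")
    stable = np.abs(np.diff(series.angles)) <= angle_threshold
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(stable)
    while i < n:
        if stable[i]:
            j = i
            while j < n and stable[j]:
                j += 1
            # epochs i .. j inclusive are one run (j - i + 1 epochs)
            n_epochs = j - i + 1
            if n_epochs * EPOCH_MINUTES >= min_duration - 1e-9:
                intervals.append((t[i], t[i] + n_epochs * EPOCH_MINUTES))
            i = j + 1
        else:
            i += 1
    return intervals


def classify_sleep_periods(
    intervals: list[tuple[float, float]],
    diary_window: tuple[float, float],
) -> list[tuple[float, float]]:
    """Intersect inactivity intervals with the diary sleep window.

    Intervals straddling a window edge are clipped at the bound; intervals
    that become shorter than the sustained-run threshold after clipping are
    retained, since the sustained rule applies at detection, before
    windowing.
    """
    bed, rise = diary_window
    if not bed < rise:
        raise ValueError("diary window must be (bed, rise) with bed < rise")
    out = []
    for start, end in intervals:
        s, e = max(start, bed), min(end, rise)
        if s < e:
            out.append((s, e))
    return out


def summarize_night(
    sleep_periods: list[tuple[float, float]],
    restorative_response: str | None = None,
    night_type: str = "",
) -> NightSummary | None:
    """Collapse a night's sleep periods into onset/wake/duration/midpoint.

    Onset is the start of the first sleep period, wake the end of the last,
    duration the sum of period lengths, and midpoint the time halfway between
    onset and wake (not weighted by within-night wakefulness).  Returns None
    when there are no sleep periods, flagging the night missing.
    """
    if not sleep_periods:
        return None
    periods = sorted(sleep_periods)
    onset = periods[0][0]
    wake = periods[-1][1]
    duration = float(sum(e - s for s, e in periods))
    if restorative_response is None:
        restorative = float("nan")
    else:
        coding = {"Refreshed": 1.0, "Tired": 0.0}
        if restorative_response not in coding:
            raise ValueError(
                f"restorative response must be 'Refreshed' or 'Tired', "
                f"got {restorative_response!r}"
            )
        restorative = coding[restorative_response]
    return NightSummary(
        onset=onset,
        wake=wake,
        duration=duration,
        midpoint=onset + (wake - onset) / 2.0,
        restorative=restorative,
        night_type=night_type,
    )


def extract_night(
    series: AngleSeries,
    diary_window: tuple[float, float],
    restorative_response: str | None = None,
    night_type: str = "",
) -> NightSummary | None:
    """Full detection pipeline for one night: detect, window, summarise."""
    intervals = detect_inactivity_periods(series)
    periods = classify_sleep_periods(intervals, diary_window)
    return summarize_night(periods, restorative_response, night_type)
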