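"""Day-type and diurnal-period assignment, boundary splitting, diurnal stats.

The four periods tile the civil day with half-open bounds:
night [00:00, 06:00), morning [06:00, 12:00), afternoon [12:00, 18:00),
evening [18:00, 24:00).  Durations crossing a boundary (including midnight)
are split at the boundary; launches are attributed to the opening instant.
"""
from __future__ import annotations

import math
from datetime import datetime, timedelta
from typing import Sequence

from .event_model import UsageInterval

PERIODS: tuple[str, ...] = ("night", "morning", "afternoon", "evening")
DAY_TYPES: tuple[str, ...] = ("weekday", "weekend")

#: Period start hours; must begin at 0 and be strictly increasing.
DEFAULT_BOUNDARIES: tuple[int, ...] = (0, 6, 12, 18)

DiurnalKey = tuple[str, str]  # (day_type, period)


def day_type(ts: datetime, weekend_days: frozenset[int]) -> str:
    """'weekend' iff the civil weekday of ts is configured as weekend."""
    return "weekend" if ts.weekday() in weekend_days else "weekday"


def period_of(ts: datetime, boundaries: Sequence[int] = DEFAULT_BOUNDARIES) -> str:
    if boundaries[0] != 0 or list(boundaries) != sorted(set(boundaries)):
        raise ValueError("boundaries must start at 0 and be strictly increasing")
    idx = 0
    for i, b in enumerate(boundaries):
        if ts.hour >= b:
            idx = i
    return PERIODS[idx]


def diurnal_key(
    ts: datetime,
    weekend_days: frozenset[int],
    boundaries: Sequence[int] = DEFAULT_BOUNDARIES,
) -> DiurnalKey:
    return day_type(ts, weekend_days), period_of(ts, boundaries)


def launch_period(
    interval: UsageInterval,
    weekend_days: frozenset[int],
    boundaries: Sequence[int] = DEFAULT_BOUNDARIES,
) -> DiurnalKey:
    """The key of the opening instant: launches count where the app opened."""
    return diurnal_key(interval.start, weekend_days, boundaries)


def _next_boundary(
    ts: datetime, boundaries: Sequence[int]
) -> datetime:
    """Earliest period boundary (including midnight) strictly after ts."""
    day = ts.replace(hour=0, minute=0, second=0, microsecond=0)
    for b in boundaries[1:]:
        cand = day + timedelta(hours=b)
        if cand > ts:
            return cand
    return day + timedelta(days=1)


def split_interval(
    interval: UsageInterval,
    weekend_days: frozenset[int],
    boundaries: Sequence[int] = DEFAULT_BOUNDARIES,
) -> list[tuple[DiurnalKey, float]]:
    """Allocate an interval's duration (seconds) to each diurnal key crossed.

    The parts sum exactly to the interval duration (integer microseconds).
    A zero-length interval yields one zero-duration part at its opening key.
    """
    if interval.end == interval.start:
        return [(diurnal_key(interval.start, weekend_days, boundaries), 0.0)]
    parts: list[tuple[DiurnalKey, float]] = []
    cur = interval.start
    while cur < interval.end:
        nb = _next_boundary(cur, boundaries)
        seg_end = min(nb, interval.end)
        micros = (seg_end - cur) // timedelta(microseconds=1)
        parts.append((diurnal_key(cur, weekend_days, boundaries), micros / 1e6))
        cur = seg_end
    return parts


def diurnal_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and population SD (divisor 4) over the four per-period values."""
    if len(values) != len(PERIODS):
        raise ValueError(f"expected {len(PERIODS)} period values, got {len(values)}")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)
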