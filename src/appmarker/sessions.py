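"""Gap-based session segmentation and micro/review/engage typing.

Consecutive usage intervals belong to one session while the device-level gap
(next start minus the latest end seen so far) stays within the 45 s threshold;
overlapping intervals count as gap 0.  Sessions are typed by total active
duration: micro <= 15 s < review <= 60 s < engage.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

from .diurnal import DEFAULT_BOUNDARIES, PERIODS, diurnal_key
from .event_model import UsageInterval

GAP_THRESHOLD = 45.0  # seconds

MICRO = "micro"
REVIEW = "review"
ENGAGE = "engage"
SESSION_TYPES: tuple[str, ...] = (MICRO, REVIEW, ENGAGE)

MICRO_MAX = 15.0  # seconds, inclusive
REVIEW_MAX = 60.0  # seconds, inclusive


def type_for_duration(active_duration: float) -> str:
    if active_duration < 0:
        raise ValueError("active_duration must be >= 0")
    if active_duration <= MICRO_MAX:
        return MICRO
    if active_duration <= REVIEW_MAX:
        return REVIEW
    return ENGAGE


@dataclass(frozen=True)
class Session:
    participant_id: str
    intervals: tuple[UsageInterval, ...]

    @property
    def start(self) -> datetime:
        return self.intervals[0].start

    @property
    def end(self) -> datetime:
        return max(iv.end for iv in self.intervals)

    @property
    def active_duration(self) -> float:
        """Sum of member interval durations (overlaps counted twice)."""
        return sum(iv.duration for iv in self.intervals)

    @property
    def type(self) -> str:
        return type_for_duration(self.active_duration)


def type_session(session: Session) -> str:
    return session.type


def segment(
    intervals: Sequence[UsageInterval], gap_threshold: float = GAP_THRESHOLD
) -> list[Session]:
    """Partition intervals (possibly several participants) into sessions.

    A new session begins iff next.start - previous_session_end > gap_threshold,
    where previous_session_end is the max end among the session's members.
    """
    by_pid: dict[str, list[UsageInterval]] = {}
    for iv in intervals:
        by_pid.setdefault(iv.participant_id, []).append(iv)

    out: list[Session] = []
    for pid in by_pid:
        ivs = sorted(by_pid[pid], key=lambda iv: (iv.start, iv.end, iv.package))
        cur: list[UsageInterval] = []
        cur_end: datetime | None = None
        for iv in ivs:
            if cur_end is not None:
                gap = max(0.0, (iv.start - cur_end).total_seconds())
                if gap > gap_threshold:
                    out.append(Session(pid, tuple(cur)))
                    cur = []
                    cur_end = None
            cur.append(iv)
            cur_end = iv.end if cur_end is None else max(cur_end, iv.end)
        if cur:
            out.append(Session(pid, tuple(cur)))
    out.sort(key=lambda s: (s.participant_id, s.start))
    return out


def session_counts(
    sessions: Iterable[Session],
    weekend_days: frozenset[int],
    boundaries: Sequence[int] = DEFAULT_BOUNDARIES,
) -> dict[str, dict[str, dict[str, int]]]:
    """Session counts by day_type x (period | 'total') x (type | 'total').

    A session is attributed to the diurnal key of its start instant.
    """
    counts: dict[str, dict[str, dict[str, int]]] = {
        dt: {slot: {t: 0 for t in (*SESSION_TYPES, "total")} for slot in (*PERIODS, "total")}
        for dt in ("weekday", "weekend")
    }
    for s in sessions:
        dt, period = diurnal_key(s.start, weekend_days, boundaries)
        for slot in (period, "total"):
            counts[dt][slot][s.type] += 1
            counts[dt][slot]["total"] += 1
    return counts
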