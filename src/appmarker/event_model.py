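"""Raw app-usage event parsing, validation, interval pairing and categorization.

Event logs are rows of (participant_id, timestamp, package, kind) where kind is
``foreground`` or ``background``.  Foreground/background pairs are turned into
:class:`UsageInterval` objects by a per-package FIFO rule; intervals are clipped
to the 7-day observation window.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Closed list of the 27 canonical app-category names.  Every catalog row must
#: use one of these; the overall-smartphone scope is handled separately.
CANONICAL_CATEGORIES: tuple[str, ...] = (
    "Art and Design",
    "Auto and Vehicles",
    "Beauty",
    "Books and Reference",
    "Business",
    "Communication",
    "Dating",
    "Education",
    "Entertainment",
    "Finance",
    "Food and Drink",
    "Games",
    "Health and Fitness",
    "House and Home",
    "Lifestyle",
    "Maps and Navigation",
    "Medical",
    "Music and Audio",
    "News and Magazines",
    "Personalization",
    "Photo and Video",
    "Productivity",
    "Shopping",
    "Social",
    "Sports",
    "Tools",
    "Weather",
)

FOREGROUND = "foreground"
BACKGROUND = "background"
_KINDS = (FOREGROUND, BACKGROUND)

_REQUIRED_COLUMNS = ("participant_id", "timestamp", "package", "kind")

#: Fraction of unparseable rows above which the whole file is rejected.
MAX_BAD_ROW_FRACTION = 0.10


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class CatalogError(ValueError):
    """Invalid app-category catalog (unknown category, conflicting duplicates)."""


@dataclass(frozen=True)
class RowError:
    """A single malformed input row, reported with its 1-based line number."""

    line: int
    message: str


@dataclass(frozen=True, slots=True)
class AppEvent:
    participant_id: str
    timestamp: datetime
    package: str
    kind: str  # foreground | background

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.package:
            raise ValueError("package must be non-empty")


@dataclass(frozen=True, slots=True)
class UsageInterval:
    """A contiguous foreground run of one app for one participant."""

    participant_id: str
    package: str
    start: datetime
    end: datetime
    category: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end precedes start")

    @property
    def duration(self) -> float:
        """Interval length in seconds."""
        return (self.end - self.start).total_seconds()


@dataclass(frozen=True)
class ObservationWindow:
    """A 7-civil-day observation window with a configurable weekend.

    ``weekend_days`` uses Python weekday indices (Monday=0).  The default
    {Friday, Saturday} matches the study country's weekend.
    """

    start: datetime
    weekend_days: frozenset[int] = frozenset({4, 5})

    def __post_init__(self) -> None:
        days = frozenset(int(d) for d in self.weekend_days)
        if not days:
            raise ValueError("weekend_days must be nonempty")
        if not days < frozenset(range(7)):
            raise ValueError("weekend_days must be a strict subset of the 7 weekdays")
        object.__setattr__(self, "weekend_days", days)

    @property
    def end(self) -> datetime:
        return self.start + timedelta(days=7)

    def contains(self, ts: datetime) -> bool:
        return self.start <= ts < self.end

    def clip(self, start: datetime, end: datetime) -> tuple[datetime, datetime] | None:
        """Clamp [start, end] to the window; None if fully outside."""
        lo = max(start, self.start)
        hi = min(end, self.end)
        if hi < lo:
            return None
        return lo, hi


class AppCatalog:
    """Mapping package -> category over the closed 27-name category list.

    Unknown packages resolve to ``fallback`` ("Tools" by default, the most
    populous category).
    """

    def __init__(self, mapping: Mapping[str, str], fallback: str = "Tools") -> None:
        if fallback not in CANONICAL_CATEGORIES:
            raise CatalogError(f"fallback category {fallback!r} is not canonical")
        bad = {c for c in mapping.values() if c not in CANONICAL_CATEGORIES}
        if bad:
            raise CatalogError(f"non-canonical categories in catalog: {sorted(bad)}")
        self._mapping = dict(mapping)
        self.fallback = fallback

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, package: str) -> bool:
        return package in self._mapping

    def category(self, package: str) -> str:
        return self._mapping.get(package, self.fallback)

    @classmethod
    def from_csv(cls, path: str | Path, fallback: str = "Tools") -> "AppCatalog":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"package", "category"} <= set(reader.fieldnames):
                raise SchemaError("catalog CSV requires columns: package,category")
            for i, row in enumerate(reader, start=2):
                pkg, cat = row["package"].strip(), row["category"].strip()
                if pkg in mapping and mapping[pkg] != cat:
                    raise CatalogError(
                        f"line {i}: package {pkg!r} mapped to both "
                        f"{mapping[pkg]!r} and {cat!r}"
                    )
                mapping[pkg] = cat
        return cls(mapping, fallback=fallback)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["package", "category"])
            for pkg in sorted(self._mapping):
                writer.writerow([pkg, self._mapping[pkg]])


def _parse_row(row: Mapping[str, str]) -> AppEvent:
    ts = datetime.fromisoformat(str(row["timestamp"]).strip())
    kind = str(row["kind"]).strip().lower()
    if kind not in _KINDS:
        raise ValueError(f"unknown event kind {row['kind']!r}")
    pkg = str(row["package"]).strip()
    if not pkg:
        raise ValueError("empty package")
    return AppEvent(
        participant_id=str(row["participant_id"]).strip(),
        timestamp=ts,
        package=pkg,
        kind=kind,
    )


def read_events(
    path: str | Path, fmt: str | None = None
) -> tuple[dict[str, list[AppEvent]], list[RowError]]:
    """Read an event log, returning events per participant plus row errors.

    Events are sorted by timestamp within each participant (background before
    foreground at equal timestamps).  Malformed rows are collected as
    :class:`RowError`; if more than :data:`MAX_BAD_ROW_FRACTION` of rows fail,
    a :class:`SchemaError` is raised instead.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".json"} else "csv"
    if fmt not in {"csv", "jsonl"}:
        raise ValueError(f"format must be csv or jsonl, got {fmt!r}")

    events: dict[str, list[AppEvent]] = {}
    errors: list[RowError] = []
    n_rows = 0

    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                logger.warning("empty event log %s", path)
                return {}, []
            missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise SchemaError(f"missing required columns: {sorted(missing)}")
            for line_no, row in enumerate(reader, start=2):
                n_rows += 1
                try:
                    ev = _parse_row(row)
                except (ValueError, KeyError, TypeError) as exc:
                    errors.append(RowError(line_no, str(exc)))
                    continue
                events.setdefault(ev.participant_id, []).append(ev)
    else:
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                n_rows += 1
                try:
                    row = json.loads(line)
                    missing = set(_REQUIRED_COLUMNS) - set(row)
                    if missing:
                        raise ValueError(f"missing keys: {sorted(missing)}")
                    ev = _parse_row(row)
                except (ValueError, KeyError, TypeError) as exc:
                    errors.append(RowError(line_no, str(exc)))
                    continue
                events.setdefault(ev.participant_id, []).append(ev)

    if n_rows == 0:
        logger.warning("empty event log %s", path)
    elif len(errors) > MAX_BAD_ROW_FRACTION * n_rows:
        raise SchemaError(
            f"{len(errors)} of {n_rows} rows failed to parse "
            f"(> {MAX_BAD_ROW_FRACTION:.0%} threshold)"
        )

    for pid in events:
        events[pid].sort(key=_event_sort_key)
    return events, errors


def _event_sort_key(ev: AppEvent) -> tuple:
    # Background sorts before foreground at equal timestamps: prevents
    # zero-length phantom overlaps when one app closes as another opens.
    return (ev.timestamp, 0 if ev.kind == BACKGROUND else 1, ev.package)


def pair_intervals(
    events: Sequence[AppEvent], window: ObservationWindow
) -> list[UsageInterval]:
    """Pair foreground/background events into usage intervals.

    Per-package FIFO matching: a foreground opens an interval, the next
    background of the same package closes it.  A second foreground for an
    already-open package closes the first interval at the new foreground's
    timestamp.  Unmatched backgrounds are dropped; intervals still open at the
    window end are closed there.  All intervals are clipped to the window.
    """
    ordered = sorted(events, key=_event_sort_key)
    open_at: dict[tuple[str, str], datetime] = {}
    out: list[UsageInterval] = []

    def emit(pid: str, pkg: str, start: datetime, end: datetime) -> None:
        clipped = window.clip(start, end)
        if clipped is None:
            return
        lo, hi = clipped
        out.append(UsageInterval(participant_id=pid, package=pkg, start=lo, end=hi))

    for ev in ordered:
        key = (ev.participant_id, ev.package)
        if ev.kind == FOREGROUND:
            if key in open_at:
                emit(ev.participant_id, ev.package, open_at[key], ev.timestamp)
            open_at[key] = ev.timestamp
        else:
            start = open_at.pop(key, None)
            if start is not None:
                emit(ev.participant_id, ev.package, start, ev.timestamp)

    for (pid, pkg), start in open_at.items():
        emit(pid, pkg, start, window.end)

    out.sort(key=lambda iv: (iv.participant_id, iv.start, iv.end, iv.package))
    return out


def categorize(
    item: UsageInterval | str, catalog: AppCatalog, fallback_category: str | None = None
) -> str:
    """Return the catalog category of an interval or package name."""
    pkg = item.package if isinstance(item, UsageInterval) else item
    if pkg in catalog:
        return catalog.category(pkg)
    return fallback_category if fallback_category is not None else catalog.fallback


def attach_categories(
    intervals: Iterable[UsageInterval], catalog: AppCatalog
) -> list[UsageInterval]:
    return [replace(iv, category=categorize(iv, catalog)) for iv in intervals]


_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


def intervals_to_csv(intervals: Iterable[UsageInterval], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "package", "start", "end", "category"])
        for iv in intervals:
            writer.writerow(
                [
                    iv.participant_id,
                    iv.package,
                    iv.start.strftime(_TS_FORMAT),
                    iv.end.strftime(_TS_FORMAT),
                    iv.category or "",
                ]
            )


def intervals_from_csv(path: str | Path) -> list[UsageInterval]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                UsageInterval(
                    participant_id=row["participant_id"],
                    package=row["package"],
                    start=datetime.strptime(row["start"], _TS_FORMAT),
                    end=datetime.strptime(row["end"], _TS_FORMAT),
                    category=row["category"] or None,
                )
            )
    return out
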