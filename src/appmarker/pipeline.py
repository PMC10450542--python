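"""End-to-end glue: event frames -> intervals -> sessions -> feature matrix."""
from __future__ import annotations

from datetime import datetime
from typing import Mapping, Sequence

import pandas as pd

from .event_model import (
    AppCatalog,
    AppEvent,
    ObservationWindow,
    UsageInterval,
    attach_categories,
    pair_intervals,
)
from .markers import AppSets, FeatureMatrix, HammingIndex, extract_features
from .sessions import Session, segment
from .synthetic import CohortData


def events_from_frame(df: pd.DataFrame) -> dict[str, list[AppEvent]]:
    """Convert an event DataFrame into per-participant AppEvent lists."""
    out: dict[str, list[AppEvent]] = {}
    for row in df.itertuples(index=False):
        ev = AppEvent(
            participant_id=str(row.participant_id),
            timestamp=datetime.fromisoformat(str(row.timestamp)),
            package=str(row.package),
            kind=str(row.kind),
        )
        out.setdefault(ev.participant_id, []).append(ev)
    return out


def build_cohort(
    events_by_pid: Mapping[str, Sequence[AppEvent]],
    catalog: AppCatalog,
    window: ObservationWindow,
) -> tuple[dict[str, list[UsageInterval]], dict[str, list[Session]]]:
    """Pair, categorize and sessionize events for every participant."""
    intervals_by_pid: dict[str, list[UsageInterval]] = {}
    sessions_by_pid: dict[str, list[Session]] = {}
    for pid, events in events_by_pid.items():
        intervals = attach_categories(pair_intervals(events, window), catalog)
        intervals_by_pid[pid] = intervals
        sessions_by_pid[pid] = segment(intervals)
    return intervals_by_pid, sessions_by_pid


def build_matrix(
    events_by_pid: Mapping[str, Sequence[AppEvent]],
    catalog: AppCatalog,
    labels: Mapping[str, int] | None,
    window: ObservationWindow,
) -> tuple[FeatureMatrix, AppSets]:
    intervals_by_pid, sessions_by_pid = build_cohort(events_by_pid, catalog, window)
    return extract_features(intervals_by_pid, sessions_by_pid, labels, window)


def matrix_from_cohort(
    cohort: CohortData, window: ObservationWindow
) -> tuple[FeatureMatrix, HammingIndex]:
    """Feature matrix plus hamming index for a synthetic cohort."""
    events_by_pid = events_from_frame(cohort.events)
    fm, app_sets = build_matrix(
        events_by_pid, cohort.app_catalog(), cohort.labels, window
    )
    return fm, HammingIndex(app_sets, fm.participants)
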