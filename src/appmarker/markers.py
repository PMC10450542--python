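"""The 864-cell behavioral feature grid: extraction, filtering, scaling.

Grid structure: (27 app categories + overall "Smartphone") x {Weekday, Weekend}
x {Duration, Launch, Number_of_Apps, Entropy, Ratio_of_Hamming}
x {6_Hour_Mean, 6_Hour_SD, Total}, plus session measures
{Number_of_Sessions, Microsession, Review_Session, Engage_Session} over the
same day types and characteristics: 28*2*5*3 + 2*4*3 = 864 features.

"Total" is the whole-day value; "6_Hour_Mean"/"6_Hour_SD" are the mean and
population SD over the four diurnal periods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diurnal import (
    DEFAULT_BOUNDARIES,
    PERIODS,
    diurnal_stats,
    launch_period,
    split_interval,
)
from .event_model import CANONICAL_CATEGORIES, ObservationWindow, UsageInterval
from .sessions import Session, session_counts

SMARTPHONE = "Smartphone"
SESSION_SCOPE = "Session"

APP_SCOPES: tuple[str, ...] = CANONICAL_CATEGORIES + (SMARTPHONE,)
DAY_TYPES: tuple[str, ...] = ("weekday", "weekend")

APP_MEASURES: tuple[str, ...] = (
    "Duration",
    "Launch",
    "Number_of_Apps",
    "Entropy",
    "Ratio_of_Hamming",
)
SESSION_MEASURES: tuple[str, ...] = (
    "Number_of_Sessions",
    "Microsession",
    "Review_Session",
    "Engage_Session",
)
_SESSION_MEASURE_KEY = {
    "Number_of_Sessions": "total",
    "Microsession": "micro",
    "Review_Session": "review",
    "Engage_Session": "engage",
}
CHARACTERISTICS: tuple[str, ...] = ("6_Hour_Mean", "6_Hour_SD", "Total")

N_FEATURES = 864


def _scope_token(scope: str) -> str:
    return scope.replace(" ", "_")


@dataclass(frozen=True)
class FeatureSpec:
    """One cell of the feature grid."""

    scope: str  # category name, "Smartphone", or "Session"
    day_type: str  # weekday | weekend
    measure: str
    characteristic: str  # 6_Hour_Mean | 6_Hour_SD | Total

    @property
    def name(self) -> str:
        return (
            f"{self.day_type.capitalize()}_{_scope_token(self.scope)}"
            f"_{self.measure}_{self.characteristic}"
        )


def enumerate_features() -> tuple[FeatureSpec, ...]:
    """The full, ordered 864-member feature enumeration."""
    specs: list[FeatureSpec] = []
    for day in DAY_TYPES:
        for scope in APP_SCOPES:
            for measure in APP_MEASURES:
                for char in CHARACTERISTICS:
                    specs.append(FeatureSpec(scope, day, measure, char))
    for day in DAY_TYPES:
        for measure in SESSION_MEASURES:
            for char in CHARACTERISTICS:
                specs.append(FeatureSpec(SESSION_SCOPE, day, measure, char))
    assert len(specs) == N_FEATURES
    return tuple(specs)


FEATURE_SPECS: tuple[FeatureSpec, ...] = enumerate_features()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in FEATURE_SPECS)


def usage_entropy(durations: Iterable[float], base: float | None = None) -> float:
    """Shannon entropy of the per-app usage-duration distribution.

    p(j) = duration(j) / sum(durations).  Natural log by default.  Zero for a
    single app and, by convention, for an empty scope.
    """
    pos = [d for d in durations if d > 0]
    total = sum(pos)
    if total <= 0 or len(pos) <= 1:
        return 0.0
    log = math.log if base is None else (lambda x: math.log(x, base))
    return -sum((d / total) * log(d / total) for d in pos)


def hamming_distance(a: frozenset, b: frozenset) -> int:
    """Symmetric-difference cardinality of two app sets."""
    return len(a ^ b)


def hamming_ratio(
    target_set: frozenset,
    depressed_sets: Sequence[frozenset],
    nondepressed_sets: Sequence[frozenset],
) -> float | None:
    """Ratio of min distance to the depressed pool over the nondepressed pool.

    Conventions: 0/0 -> 1.0 (equally unique in both groups); x/0 with x>0 ->
    x+1 (smoothed, monotone in x).  Returns None when either pool is empty.
    The caller is responsible for excluding the target's own set from pools.
    """
    if not depressed_sets or not nondepressed_sets:
        return None
    d = min(hamming_distance(target_set, s) for s in depressed_sets)
    nd = min(hamming_distance(target_set, s) for s in nondepressed_sets)
    if nd == 0:
        return 1.0 if d == 0 else float(d + 1)
    return d / nd


# --------------------------------------------------------------------------
# app-set bookkeeping for hamming features

SLOTS: tuple[str, ...] = PERIODS + ("total",)

#: app_sets maps (scope, day_type, slot) -> {participant_id: frozenset(packages)}
AppSets = dict[tuple[str, str, str], dict[str, frozenset]]


class HammingIndex:
    """Precomputed pairwise app-set distances, for fast per-fold ratios.

    App sets are packed into uint64 bitmasks over each key's app universe so
    the full pairwise symmetric-difference matrix is one vectorized popcount.
    """

    def __init__(self, app_sets: AppSets, participants: Sequence[str]) -> None:
        self.participants = list(participants)
        self._pos = {p: i for i, p in enumerate(self.participants)}
        n = len(self.participants)
        self.dist: dict[tuple[str, str, str], np.ndarray] = {}
        self.scopes = sorted({k[0] for k in app_sets}) if app_sets else []
        for key, sets_by_pid in app_sets.items():
            universe = sorted(set().union(*sets_by_pid.values())) if sets_by_pid else []
            if not universe:
                self.dist[key] = np.zeros((n, n), dtype=np.int32)
                continue
            app_pos = {a: i for i, a in enumerate(universe)}
            n_words = (len(universe) + 63) // 64
            masks = np.zeros((n, n_words), dtype=np.uint64)
            for pid, apps in sets_by_pid.items():
                row = self._pos[pid]
                for a in apps:
                    bit = app_pos[a]
                    masks[row, bit // 64] |= np.uint64(1 << (bit % 64))
            xor = masks[:, None, :] ^ masks[None, :, :]
            self.dist[key] = np.bitwise_count(xor).sum(axis=2).astype(np.int32)

    def _min_dist(
        self, key: tuple[str, str, str], pool: np.ndarray
    ) -> np.ndarray:
        """Per-participant min distance to pool members, excluding self."""
        n = len(self.participants)
        if pool.size == 0:
            return np.full(n, np.nan)
        sub = self.dist[key][:, pool].astype(float)
        for col, row in enumerate(pool):
            sub[row, col] = np.inf
        out = sub.min(axis=1)
        out[~np.isfinite(out)] = np.nan
        return out

    def ratio_columns(
        self, labels: Mapping[str, int], scopes: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Hamming-ratio feature columns for every participant.

        ``labels`` defines the comparator pools (typically training-fold
        participants only); each participant's own set is always excluded from
        its pools.  Undefined ratios are NaN.
        """
        dep = np.array([self._pos[p] for p, y in labels.items() if y == 1], dtype=int)
        nd = np.array([self._pos[p] for p, y in labels.items() if y == 0], dtype=int)
        scopes = list(scopes) if scopes is not None else self.scopes
        cols: dict[str, np.ndarray] = {}
        for scope in scopes:
            for day in DAY_TYPES:
                if (scope, day, "total") not in self.dist:
                    continue
                period_ratios = []
                for slot in SLOTS:
                    key = (scope, day, slot)
                    d = self._min_dist(key, dep)
                    ndist = self._min_dist(key, nd)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ratio = np.where(
                            ndist == 0,
                            np.where(d == 0, 1.0, d + 1.0),
                            d / ndist,
                        )
                    ratio = np.where(np.isnan(d) | np.isnan(ndist), np.nan, ratio)
                    if slot == "total":
                        total_ratio = ratio
                    else:
                        period_ratios.append(ratio)
                stacked = np.vstack(period_ratios)
                prefix = f"{day.capitalize()}_{_scope_token(scope)}_Ratio_of_Hamming"
                cols[f"{prefix}_6_Hour_Mean"] = stacked.mean(axis=0)
                cols[f"{prefix}_6_Hour_SD"] = stacked.std(axis=0)
                cols[f"{prefix}_Total"] = total_ratio
        return pd.DataFrame(cols, index=self.participants)


# --------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Participant x feature realization of the grid, plus sparsity metadata."""

    df: pd.DataFrame
    user_frac: pd.Series  # per-category fraction of participants using it

    @property
    def participants(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "participant_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="participant_id")
        df.index = df.index.astype(str)
        return cls(df=df, user_frac=pd.Series(dtype=float))


def extract_features(
    intervals_by_pid: Mapping[str, Sequence[UsageInterval]],
    sessions_by_pid: Mapping[str, Sequence[Session]],
    labels: Mapping[str, int] | None,
    window: ObservationWindow,
    boundaries: Sequence[int] = DEFAULT_BOUNDARIES,
) -> tuple[FeatureMatrix, AppSets]:
    """Compute the full 864-column feature matrix for a cohort.

    Intervals must carry categories (see ``attach_categories``).  ``labels``
    (participant -> 0/1) feeds the hamming-ratio comparator pools; when None,
    hamming columns are NaN.  Absent usage yields 0 for counts and durations
    and the documented conventions for entropy and hamming.
    """
    participants = list(intervals_by_pid)
    wk = window.weekend_days

    # per-(scope, day, period) per-app durations and launch counts, per pid
    appdur: dict[str, dict[tuple[str, str, str], dict[str, float]]] = {
        pid: {} for pid in participants
    }
    launches: dict[str, dict[tuple[str, str, str], int]] = {pid: {} for pid in participants}

    for pid, intervals in intervals_by_pid.items():
        ad = appdur[pid]
        lc = launches[pid]
        for iv in intervals:
            if iv.category is None:
                raise ValueError(
                    f"interval for {iv.package!r} lacks a category; "
                    "run attach_categories first"
                )
            scopes = (iv.category, SMARTPHONE)
            for (dt, period), seconds in split_interval(iv, wk, boundaries):
                for scope in scopes:
                    bucket = ad.setdefault((scope, dt, period), {})
                    bucket[iv.package] = bucket.get(iv.package, 0.0) + seconds
            ldt, lper = launch_period(iv, wk, boundaries)
            for scope in scopes:
                key = (scope, ldt, lper)
                lc[key] = lc.get(key, 0) + 1
                ad.setdefault(key, {}).setdefault(iv.package, 0.0)

    app_sets: AppSets = {
        (scope, day, slot): {} for scope in APP_SCOPES for day in DAY_TYPES for slot in SLOTS
    }

    values = np.zeros((len(participants), N_FEATURES))
    col_idx = {name: i for i, name in enumerate(FEATURE_NAMES)}

    for row, pid in enumerate(participants):
        ad = appdur[pid]
        lc = launches[pid]
        for scope in APP_SCOPES:
            for day in DAY_TYPES:
                per_dur, per_launch, per_napps, per_ent = [], [], [], []
                union: set[str] = set()
                total_by_app: dict[str, float] = {}
                for period in PERIODS:
                    bucket = ad.get((scope, day, period), {})
                    per_dur.append(sum(bucket.values()))
                    per_launch.append(lc.get((scope, day, period), 0))
                    per_napps.append(len(bucket))
                    per_ent.append(usage_entropy(bucket.values()))
                    union.update(bucket)
                    for a, d in bucket.items():
                        total_by_app[a] = total_by_app.get(a, 0.0) + d
                    app_sets[(scope, day, period)][pid] = frozenset(bucket)
                app_sets[(scope, day, "total")][pid] = frozenset(union)

                prefix = f"{day.capitalize()}_{_scope_token(scope)}"
                for measure, per_vals, total_val in (
                    ("Duration", per_dur, sum(per_dur)),
                    ("Launch", per_launch, sum(per_launch)),
                    ("Number_of_Apps", per_napps, len(union)),
                    ("Entropy", per_ent, usage_entropy(total_by_app.values())),
                ):
                    mean, sd = diurnal_stats(per_vals)
                    values[row, col_idx[f"{prefix}_{measure}_6_Hour_Mean"]] = mean
                    values[row, col_idx[f"{prefix}_{measure}_6_Hour_SD"]] = sd
                    values[row, col_idx[f"{prefix}_{measure}_Total"]] = total_val

        counts = session_counts(sessions_by_pid.get(pid, ()), wk, boundaries)
        for day in DAY_TYPES:
            for measure in SESSION_MEASURES:
                tkey = _SESSION_MEASURE_KEY[measure]
                per_vals = [counts[day][p][tkey] for p in PERIODS]
                mean, sd = diurnal_stats(per_vals)
                prefix = f"{day.capitalize()}_{SESSION_SCOPE}"
                values[row, col_idx[f"{prefix}_{measure}_6_Hour_Mean"]] = mean
                values[row, col_idx[f"{prefix}_{measure}_6_Hour_SD"]] = sd
                values[row, col_idx[f"{prefix}_{measure}_Total"]] = counts[day]["total"][tkey]

    df = pd.DataFrame(values, index=participants, columns=list(FEATURE_NAMES))

    if labels is not None:
        index = HammingIndex(app_sets, participants)
        ham = index.ratio_columns({p: labels[p] for p in participants})
        df[ham.columns] = ham
    else:
        for name in FEATURE_NAMES:
            if "_Ratio_of_Hamming_" in name:
                df[name] = np.nan

    # sparsity metadata: a participant "uses" a category if its 7-day total
    # duration across both day types is positive
    frac = {}
    for cat in CANONICAL_CATEGORIES:
        tok = _scope_token(cat)
        tot = (
            df[f"Weekday_{tok}_Duration_Total"] + df[f"Weekend_{tok}_Duration_Total"]
        )
        frac[cat] = float((tot > 0).mean()) if len(df) else 0.0

    return FeatureMatrix(df=df, user_frac=pd.Series(frac)), app_sets


def sparsity_filter(matrix: FeatureMatrix, min_user_frac: float = 0.5) -> FeatureMatrix:
    """Drop all features of categories used by < min_user_frac of participants.

    Smartphone- and session-scope features are always retained.
    """
    dropped = {
        _scope_token(cat)
        for cat, frac in matrix.user_frac.items()
        if frac < min_user_frac
    }

    def keep(name: str) -> bool:
        for day in ("Weekday_", "Weekend_"):
            if name.startswith(day):
                rest = name[len(day):]
                return not any(rest.startswith(tok + "_") for tok in dropped)
        return True

    cols = [c for c in matrix.df.columns if keep(c)]
    return FeatureMatrix(df=matrix.df[cols], user_frac=matrix.user_frac)


def standardize(
    train: pd.DataFrame, apply: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-feature (x - train mean) / train SD using train statistics only.

    Zero-variance features map to 0; NaN cells (undefined hamming ratios) are
    zero-imputed after scaling.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)

    def scale(df: pd.DataFrame) -> pd.DataFrame:
        out = (df - mean) / sd.replace(0.0, np.nan)
        out[sd.index[sd == 0.0]] = 0.0
        return out.fillna(0.0)

    return scale(train), (scale(apply) if apply is not None else None)
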