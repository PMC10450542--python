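"""Synthetic 7-day app-usage cohorts with known group structure.

Generation is top-down: per-participant generation parameters (app-choice
concentration, category inventories, session rates) are drawn from
group-shifted distributions controlled by standardized effect sizes, then a
sessionized foreground/background event stream is realized.  The intended
group differences are emitted as a ground-truth marker table so that
extraction and selection can be tested by parameter recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .event_model import AppCatalog, ObservationWindow

#: Default planted effects (standardized shift; positive = depressed higher).
DEFAULT_EFFECTS: dict[str, float] = {
    "weekday_education_duration": -1.5,
    "weekend_photo_video_napps_sd": 1.5,
    "weekday_smartphone_entropy": -1.5,
    "weekday_communication_diversity": 1.5,
}

#: Feature-grid column targeted by each effect key.
TRUTH_FEATURES: dict[str, str] = {
    "weekday_education_duration": "Weekday_Education_Duration_Total",
    "weekend_photo_video_napps_sd": "Weekend_Photo_and_Video_Number_of_Apps_6_Hour_SD",
    "weekday_smartphone_entropy": "Weekday_Smartphone_Entropy_Total",
    "weekday_communication_diversity": "Weekday_Communication_Number_of_Apps_Total",
}

#: Categories in the synthetic app universe and their pool sizes.
SYNTH_CATEGORIES: dict[str, int] = {
    "Communication": 8,
    "Social": 6,
    "Tools": 6,
    "Education": 6,
    "Photo and Video": 8,
    "Games": 5,
    "Productivity": 5,
    "Entertainment": 5,
}

_BASE_CATEGORY_WEIGHTS: dict[str, float] = {
    "Communication": 0.26,
    "Social": 0.18,
    "Tools": 0.10,
    "Education": 0.12,
    "Photo and Video": 0.10,
    "Games": 0.08,
    "Productivity": 0.08,
    "Entertainment": 0.08,
}

#: Mean foreground+background events per usage session (2 per interval,
#: ~1.6 intervals per session).
_EVENTS_PER_SESSION = 3.2

#: Below this weekly event volume sessions effectively vanish.
MIN_EVENTS_PER_PHONE = 60.0


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectConfig:
    """Cohort-level generation knobs: prevalence, volume, planted effects."""

    prevalence: float = 0.5
    events_per_phone: float = 8174.04
    effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    diurnal_intensity: tuple[float, float, float, float] = (0.10, 0.25, 0.30, 0.35)
    session_type_mix: tuple[float, float, float] = (0.35, 0.30, 0.35)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise GenerationError("prevalence must lie in (0, 1)")
        if self.events_per_phone <= 0:
            raise GenerationError("events_per_phone must be positive")
        if any(not math.isfinite(v) for v in self.effects.values()):
            raise GenerationError("effect sizes must be finite")
        unknown = set(self.effects) - set(DEFAULT_EFFECTS)
        if unknown:
            raise GenerationError(f"unknown effect keys: {sorted(unknown)}")
        for vec in (self.diurnal_intensity, self.session_type_mix):
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise GenerationError("mixture weights must be a probability vector")


def scale(config: EffectConfig, factor: float) -> EffectConfig:
    """Scale the event volume, preserving the planted marker structure."""
    if factor <= 0:
        raise GenerationError("scale factor must be positive")
    return replace(config, events_per_phone=config.events_per_phone * factor)


@dataclass
class CohortData:
    events: pd.DataFrame  # participant_id, timestamp, package, kind
    catalog: pd.DataFrame  # package, category
    phq9: pd.DataFrame  # participant_id, item1..item9
    truth: pd.DataFrame  # effect, feature, d, higher_group
    labels: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.catalog.to_csv(outdir / "catalog.csv", index=False)
        self.phq9.to_csv(outdir / "phq9.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)

    def app_catalog(self) -> AppCatalog:
        return AppCatalog(dict(zip(self.catalog["package"], self.catalog["category"])))


def _package(category: str, i: int) -> str:
    return f"com.synth.{category.lower().replace(' ', '.')}.app{i:02d}"


def _items_for_total(total: int, rng: np.random.Generator) -> list[int]:
    items = [0] * 9
    for _ in range(total):
        open_slots = [i for i in range(9) if items[i] < 3]
        items[open_slots[rng.integers(0, len(open_slots))]] += 1
    return items


def _round_ms(ts):
    return ts.replace(microsecond=(ts.microsecond // 1000) * 1000)


def generate(
    n_participants: int,
    window: ObservationWindow,
    config: EffectConfig | None = None,
    seed: int = 0,
) -> CohortData:
    """Generate a labeled synthetic cohort of 7-day event streams.

    Returns event logs, an app catalog, PHQ-9 responses consistent with the
    drawn labels, and the ground-truth table of planted marker effects.
    """
    if n_participants < 4:
        raise GenerationError("need at least 4 participants")
    config = config if config is not None else EffectConfig()
    if config.events_per_phone < MIN_EVENTS_PER_PHONE:
        raise GenerationError(
            f"event volume {config.events_per_phone:.0f}/phone is too low for "
            "sessions to form; increase the scale factor"
        )
    rng = np.random.default_rng(seed)

    # app universe and catalog
    apps_by_cat = {
        cat: [_package(cat, i) for i in range(size)]
        for cat, size in SYNTH_CATEGORIES.items()
    }
    catalog_rows = [
        {"package": pkg, "category": cat}
        for cat, pkgs in apps_by_cat.items()
        for pkg in pkgs
    ]

    labels_arr = (rng.random(n_participants) < config.prevalence).astype(int)
    # guarantee at least two members per class
    for cls in (0, 1):
        while (labels_arr == cls).sum() < 2:
            flip = rng.integers(0, n_participants)
            if labels_arr[flip] != cls:
                labels_arr[flip] = cls

    d_edu = config.effects.get("weekday_education_duration", 0.0)
    d_pv = config.effects.get("weekend_photo_video_napps_sd", 0.0)
    d_ent = config.effects.get("weekday_smartphone_entropy", 0.0)
    d_comm = config.effects.get("weekday_communication_diversity", 0.0)

    sessions_per_day = config.events_per_phone / (7 * _EVENTS_PER_SESSION)

    event_rows: list[dict] = []
    phq_rows: list[dict] = []
    labels: dict[str, int] = {}

    for idx in range(n_participants):
        pid = f"P{idx:03d}"
        dep = int(labels_arr[idx])
        sgn = 1.0 if dep else -1.0
        labels[pid] = dep

        total = int(rng.integers(10, 28)) if dep else int(rng.integers(0, 10))
        items = _items_for_total(total, rng)
        phq_rows.append({"participant_id": pid, **{f"item{i+1}": v for i, v in enumerate(items)}})

        # per-category inventories; communication size carries the diversity effect
        inventory: dict[str, list[str]] = {}
        for cat, pool in apps_by_cat.items():
            if cat == "Communication":
                lam = 3.0 * math.exp(0.35 * d_comm * sgn)
                size = int(np.clip(rng.poisson(lam) + 1, 1, len(pool)))
            else:
                size = int(np.clip(rng.poisson(2.0) + 1, 1, len(pool)))
            chosen = rng.choice(len(pool), size=size, replace=False)
            inventory[cat] = [pool[i] for i in sorted(chosen)]

        # app-choice concentration: smaller Dirichlet alpha -> lower entropy
        alpha_weekday = float(np.clip(1.5 * math.exp(0.6 * d_ent * sgn), 0.05, 50.0))
        weights: dict[str, dict[str, np.ndarray]] = {}
        for day_kind, alpha in (("weekday", alpha_weekday), ("weekend", 1.5)):
            weights[day_kind] = {
                cat: rng.dirichlet(np.full(len(apps), alpha))
                for cat, apps in inventory.items()
            }

        m_edu = math.exp(0.30 * d_edu * sgn)

        # low-entropy group funnels weekday usage through one favorite app per
        # category (keeps category-level durations intact, skews per-app mass)
        routed = d_ent != 0.0 and (dep == 1) == (d_ent < 0)
        route_prob = min(0.85, 0.40 * abs(d_ent)) if routed else 0.0

        def pick_app(cat: str, day_kind: str) -> str:
            if day_kind == "weekday" and route_prob and rng.random() < route_prob:
                return inventory[cat][0]
            w = weights[day_kind][cat]
            return inventory[cat][int(rng.choice(len(w), p=w))]

        def emit_session(day_start, period_idx: int, cat: str, day_kind: str,
                         duration: float, app: str | None = None) -> None:
            offset = rng.uniform(0, 6 * 3600)
            t = day_start + timedelta(hours=6 * period_idx, seconds=offset)
            n_int = int(min(rng.geometric(0.6), 3))
            shares = rng.dirichlet(np.ones(n_int))
            for share in shares:
                pkg = app if app is not None else pick_app(cat, day_kind)
                dur = max(1.0, float(share * duration))
                start = _round_ms(t)
                end = _round_ms(t + timedelta(seconds=dur))
                event_rows.append(
                    {"participant_id": pid, "timestamp": start.isoformat(timespec="milliseconds"),
                     "package": pkg, "kind": "foreground"}
                )
                event_rows.append(
                    {"participant_id": pid, "timestamp": end.isoformat(timespec="milliseconds"),
                     "package": pkg, "kind": "background"}
                )
                t = end + timedelta(seconds=rng.uniform(1, 40))

        weekend_dates = []
        for day in range(7):
            day_start = window.start + timedelta(days=day)
            day_kind = "weekend" if day_start.weekday() in window.weekend_days else "weekday"
            if day_kind == "weekend":
                weekend_dates.append(day_start)

            # the education effect acts on durations only, so launch-based
            # education features stay flat between groups
            cats = list(_BASE_CATEGORY_WEIGHTS)
            probs = np.array([_BASE_CATEGORY_WEIGHTS[c] for c in cats])
            probs /= probs.sum()

            n_sessions = rng.poisson(sessions_per_day)
            period_alloc = rng.multinomial(n_sessions, config.diurnal_intensity)
            for period_idx, count in enumerate(period_alloc):
                for _ in range(count):
                    cat = cats[int(rng.choice(len(cats), p=probs))]
                    dur_mult = m_edu if (cat == "Education" and day_kind == "weekday") else 1.0
                    u = rng.random()
                    mix = config.session_type_mix
                    if u < mix[0]:
                        base = rng.uniform(3, 15)
                    elif u < mix[0] + mix[1]:
                        base = rng.uniform(16, 60)
                    else:
                        base = min(61 + rng.exponential(240), 2400.0)
                    emit_session(day_start, period_idx, cat, day_kind,
                                 duration=base * dur_mult)

        # weekend photo/video dispersion effect: depressed concentrate many
        # distinct apps in one period; nondepressed spread one app evenly
        if d_pv != 0.0 and weekend_dates:
            pv_pool = apps_by_cat["Photo and Video"]
            if bool(dep) == (d_pv > 0):
                # burst of distinct photo/video apps inside a single period
                n_distinct = min(len(pv_pool), max(3, round(2 + 1.5 * abs(d_pv))))
                chosen = rng.choice(len(pv_pool), size=n_distinct, replace=False)
                day_start = weekend_dates[int(rng.integers(0, len(weekend_dates)))]
                period_idx = int(rng.integers(0, 4))
                for j in chosen:
                    emit_session(
                        day_start, period_idx, "Photo and Video", "weekend",
                        duration=rng.uniform(20, 60), app=pv_pool[j],
                    )
            else:
                # comparable distinct-app count, spread evenly over periods
                chosen = rng.choice(len(pv_pool), size=4, replace=False)
                for day_start in weekend_dates:
                    for period_idx in range(4):
                        emit_session(
                            day_start, period_idx, "Photo and Video", "weekend",
                            duration=rng.uniform(20, 60),
                            app=pv_pool[chosen[period_idx]],
                        )

    truth_rows = []
    for key, d in config.effects.items():
        if d == 0.0:
            continue
        truth_rows.append(
            {
                "effect": key,
                "feature": TRUTH_FEATURES[key],
                "d": d,
                "higher_group": "depressed" if d > 0 else "nondepressed",
            }
        )

    events = pd.DataFrame(
        event_rows, columns=["participant_id", "timestamp", "package", "kind"]
    ).sort_values(["participant_id", "timestamp", "kind"], ignore_index=True)
    return CohortData(
        events=events,
        catalog=pd.DataFrame(catalog_rows, columns=["package", "category"]),
        phq9=pd.DataFrame(phq_rows),
        truth=pd.DataFrame(truth_rows, columns=["effect", "feature", "d", "higher_group"]),
        labels=labels,
    )
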