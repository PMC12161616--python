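"""Minute intensity classification and daily physical-activity summaries.

Intensity thresholds operate on the per-minute MAD of the acceleration
magnitude.  The shipped defaults are documented placeholders (the published
wrist cut-points they stand in for are configuration, not code); every
group-level result downstream is threshold-independent.

A *sedentary break* is counted per 30-minute window of awake time: awake
time is partitioned into consecutive non-overlapping 30-minute windows
anchored at waketime (a trailing partial window is ignored), and a window
counts iff it contains at least 2 consecutive non-sedentary minutes.  A
16-hour awake day therefore has at most 32 breaks.  If no qualifying run has
occurred within the first 25 minutes of a window, a sedentary alert fires.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .minute_features import MinuteRecord
from .stream_ingest import MINUTES_PER_DAY

__all__ = [
    "Intensity",
    "ThresholdConfig",
    "GoalSet",
    "DayRecord",
    "classify_intensity",
    "classify_day",
    "mvpa_minutes",
    "sedentary_breaks",
    "alert_check",
    "day_alerts",
    "goal_progress",
    "summarize_day",
    "ALERT_LEAD_MINUTES",
    "BREAK_WINDOW_MINUTES",
    "METERS_PER_MILE",
]

BREAK_WINDOW_MINUTES = 30
ALERT_LEAD_MINUTES = 25
MIN_BREAK_RUN = 2
METERS_PER_MILE = 1609.344


class Intensity(IntEnum):
    """Minute intensity label; NULL marks minutes without watch data."""

    NULL = -1
    SEDENTARY = 0
    LIGHT = 1
    MVPA = 2


@dataclass(frozen=True)
class ThresholdConfig:
    """MAD cut-points in g.  Defaults are placeholders, not validated.

    MAD < sedentary_ceiling            -> sedentary
    sedentary_ceiling <= MAD < floor   -> light
    MAD >= mvpa_floor                  -> mvpa
    """

    sedentary_ceiling_g: float = 0.02
    mvpa_floor_g: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.sedentary_ceiling_g < self.mvpa_floor_g:
            raise ValueError("need 0 < sedentary_ceiling < mvpa_floor")


@dataclass(frozen=True)
class GoalSet:
    """Daily targets; None means the goal is unset."""

    energy_kcal: float | None = None
    distance_miles: float | None = None
    mvpa_minutes: float | None = None
    sedentary_breaks: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value is not None and not value > 0:
                raise ValueError(f"goal target {name} must be positive (got {value})")


@dataclass
class DayRecord:
    """The six daily PA measures plus coverage, alerts and goal progress."""

    day_date: dt.date
    energy_kcal: float
    distance_m: float
    mvpa_minutes: int
    sedentary_breaks: int
    push_total: int
    rotations_total: float
    coverage: float
    alerts: list[int] = field(default_factory=list)  # alert minutes-of-day
    goal_progress: dict[str, float] = field(default_factory=dict)
    hr_last: float | None = None
    n_nonnull_minutes: int = 0
    n_nonsedentary_minutes: int = 0

    @property
    def distance_miles(self) -> float:
        return self.distance_m / METERS_PER_MILE

    def __post_init__(self) -> None:
        if min(self.energy_kcal, self.distance_m, self.push_total) < 0:
            raise ValueError("daily totals must be non-negative")
        if self.mvpa_minutes > self.n_nonnull_minutes:
            raise ValueError("mvpa minutes cannot exceed non-null minutes")


def classify_intensity(
    mad_g: float | None, cfg: ThresholdConfig = ThresholdConfig()
) -> Intensity:
    """Label one minute; a MAD exactly at the MVPA floor is MVPA."""
    if mad_g is None:
        return Intensity.NULL
    if mad_g < cfg.sedentary_ceiling_g:
        return Intensity.SEDENTARY
    if mad_g < cfg.mvpa_floor_g:
        return Intensity.LIGHT
    return Intensity.MVPA


def classify_day(
    records: list[MinuteRecord], cfg: ThresholdConfig = ThresholdConfig()
) -> np.ndarray:
    """(1440,) int array of Intensity values for a day of minute records."""
    if len(records) != MINUTES_PER_DAY:
        raise ValueError("expected one record per minute of the day")
    return np.array(
        [int(classify_intensity(r.mad, cfg)) for r in records], dtype=int
    )


def mvpa_minutes(labels: np.ndarray) -> int:
    """Count of MVPA-labeled minutes in a 1440-long label sequence."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (MINUTES_PER_DAY,):
        raise ValueError("labels must have length 1440")
    return int(np.sum(labels == Intensity.MVPA))


def _nonsedentary_mask(labels: np.ndarray, break_rule: str) -> np.ndarray:
    # Null minutes count as sedentary here (conservative).
    labels = np.asarray(labels, dtype=int)
    if break_rule == "nonsedentary":
        return (labels == Intensity.LIGHT) | (labels == Intensity.MVPA)
    if break_rule == "mvpa_only":
        return labels == Intensity.MVPA
    raise ValueError("break_rule must be 'nonsedentary' or 'mvpa_only'")


def _has_qualifying_run(active: np.ndarray, min_run: int = MIN_BREAK_RUN) -> bool:
    run = 0
    for flag in active:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def sedentary_breaks(
    labels: np.ndarray,
    waketime_minute: int,
    bedtime_minute: int,
    break_rule: str = "nonsedentary",
) -> int:
    """Number of awake 30-minute windows containing a sedentary break.

    Windows are anchored at waketime and non-overlapping; a trailing window
    shorter than 30 minutes is ignored.  A window contains a break iff at
    least ``MIN_BREAK_RUN`` consecutive minutes inside it are non-sedentary
    under ``break_rule``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (MINUTES_PER_DAY,):
        raise ValueError("labels must have length 1440")
    if not 0 <= waketime_minute < bedtime_minute <= MINUTES_PER_DAY:
        raise ValueError("need 0 <= waketime < bedtime <= 1440")
    active = _nonsedentary_mask(labels, break_rule)
    n_windows = (bedtime_minute - waketime_minute) // BREAK_WINDOW_MINUTES
    count = 0
    for w in range(n_windows):
        lo = waketime_minute + w * BREAK_WINDOW_MINUTES
        if _has_qualifying_run(active[lo : lo + BREAK_WINDOW_MINUTES]):
            count += 1
    return count


def alert_check(window_labels: np.ndarray, break_rule: str = "nonsedentary") -> bool:
    """True (alert) iff the first 25 minutes of a window contain no break run."""
    window_labels = np.asarray(window_labels, dtype=int)
    if window_labels.shape[0] < ALERT_LEAD_MINUTES:
        raise ValueError(f"need at least {ALERT_LEAD_MINUTES} minute labels")
    active = _nonsedentary_mask(window_labels[:ALERT_LEAD_MINUTES], break_rule)
    return not _has_qualifying_run(active)


def day_alerts(
    labels: np.ndarray,
    waketime_minute: int,
    bedtime_minute: int,
    break_rule: str = "nonsedentary",
) -> list[int]:
    """Minutes-of-day at which a sedentary alert fires (25 min into a window)."""
    labels = np.asarray(labels, dtype=int)
    alerts: list[int] = []
    n_windows = (bedtime_minute - waketime_minute) // BREAK_WINDOW_MINUTES
    for w in range(n_windows):
        lo = waketime_minute + w * BREAK_WINDOW_MINUTES
        if alert_check(labels[lo : lo + BREAK_WINDOW_MINUTES], break_rule):
            alerts.append(lo + ALERT_LEAD_MINUTES)
    return alerts


def goal_progress(day: "DayRecord", goals: GoalSet) -> dict[str, float]:
    """Raw achieved/target fraction per set goal (display is capped at 1)."""
    achieved = {
        "energy_kcal": day.energy_kcal,
        "distance_miles": day.distance_miles,
        "mvpa_minutes": float(day.mvpa_minutes),
        "sedentary_breaks": float(day.sedentary_breaks),
    }
    progress: dict[str, float] = {}
    for name, target in goals.__dict__.items():
        if target is None:
            continue
        progress[name] = achieved[name] / target
    return progress


def display_progress(progress: dict[str, float]) -> dict[str, float]:
    """Progress-bar view: fractions capped at 100 %."""
    return {name: min(frac, 1.0) for name, frac in progress.items()}


def summarize_day(
    records: list[MinuteRecord],
    day_date: dt.date,
    waketime_minute: int,
    bedtime_minute: int,
    cfg: ThresholdConfig = ThresholdConfig(),
    goals: GoalSet | None = None,
    break_rule: str = "nonsedentary",
    coverage_value: float | None = None,
) -> DayRecord:
    """Roll one day of minute records up into the daily PA measures."""
    labels = classify_day(records, cfg)
    nonnull = int(np.sum(labels != Intensity.NULL))
    hr_values = [r.hr_last for r in records if r.hr_last is not None]
    if coverage_value is None:
        coverage_value = nonnull / MINUTES_PER_DAY
    day = DayRecord(
        day_date=day_date,
        energy_kcal=float(sum(r.energy_kcal for r in records)),
        distance_m=float(sum(r.distance_m for r in records)),
        mvpa_minutes=mvpa_minutes(labels),
        sedentary_breaks=sedentary_breaks(
            labels, waketime_minute, bedtime_minute, break_rule
        ),
        push_total=int(sum(r.pushes for r in records)),
        rotations_total=float(sum(r.rotations for r in records)),
        coverage=float(coverage_value),
        alerts=day_alerts(labels, waketime_minute, bedtime_minute, break_rule),
        hr_last=hr_values[-1] if hr_values else None,
        n_nonnull_minutes=nonnull,
        n_nonsedentary_minutes=int(
            np.sum((labels == Intensity.LIGHT) | (labels == Intensity.MVPA))
        ),
    )
    if goals is not None:
        day.goal_progress = goal_progress(day, goals)
    return day
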