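"""Synthetic free-living activity days with ground truth.

A day is scheduled as non-overlapping intensity bouts tiling the awake
window, then rendered into realistic multi-rate sensor streams:

* 30 Hz triaxial acceleration whose per-minute magnitude MAD is steered
  into a per-intensity band (a slow sinusoid with solved amplitude, so
  noise-free renders classify back to their scheduled labels exactly);
* propulsion strokes as ~0.4 s half-sine acceleration bursts at the
  scheduled per-minute rate;
* 1 Hz heart rate with intensity-dependent mean and AR(1) noise;
* 5 Hz wheel-rotation windows carrying the scheduled rotation counts
  (the wheel sensor's gyroscope only runs while the chair moves);
* a hard watch-stream truncation at waketime + battery life (the wheel
  sensor's month-scale battery is unaffected).

Everything is deterministic under a fixed seed.  This is plumbing for
testing the computation stack, not physiologically validated synthesis.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .daily_metrics import Intensity, ThresholdConfig
from .stream_ingest import (
    MINUTES_PER_DAY,
    DailyLogEntry,
    SensorStreams,
    write_daily_log,
    write_streams,
)
from .study_analysis import PhaseSummary

__all__ = [
    "Bout",
    "ActivitySchedule",
    "DeviceProfile",
    "ScheduleParams",
    "generate_schedule",
    "render_streams",
    "generate_table2_like_cohort",
    "write_simulation",
]

_INTENSITIES = (Intensity.SEDENTARY, Intensity.LIGHT, Intensity.MVPA)


@dataclass(frozen=True)
class Bout:
    start_minute: int
    duration_minutes: int
    intensity: Intensity
    propulsion: bool = False
    pushes_per_minute: int = 0
    rotations_per_minute: int = 0

    def __post_init__(self) -> None:
        if self.duration_minutes < 1:
            raise ValueError("bout duration must be at least 1 minute")
        if not self.propulsion and (self.pushes_per_minute or self.rotations_per_minute):
            raise ValueError("pushes/rotations must be 0 without propulsion")
        if self.pushes_per_minute < 0 or self.rotations_per_minute < 0:
            raise ValueError("pushes/rotations must be non-negative")


@dataclass
class ActivitySchedule:
    """Ground-truth day plan: bouts tile the awake window exactly."""

    participant_id: str
    day_date: dt.date
    waketime_minute: int
    bedtime_minute: int
    bouts: list[Bout]
    typical_day: bool = True

    def __post_init__(self) -> None:
        cursor = self.waketime_minute
        for bout in self.bouts:
            if bout.start_minute != cursor:
                raise ValueError("bouts must tile the awake window without overlap")
            cursor += bout.duration_minutes
        if cursor != self.bedtime_minute:
            raise ValueError("bouts must end exactly at bedtime")

    def minute_labels(self) -> np.ndarray:
        """(1440,) scheduled intensity per minute; sleep counts as sedentary."""
        labels = np.full(MINUTES_PER_DAY, int(Intensity.SEDENTARY), dtype=int)
        for bout in self.bouts:
            labels[bout.start_minute : bout.start_minute + bout.duration_minutes] = int(
                bout.intensity
            )
        return labels

    def scheduled_mvpa_minutes(self) -> int:
        return sum(
            b.duration_minutes for b in self.bouts if b.intensity == Intensity.MVPA
        )

    def scheduled_pushes(self) -> np.ndarray:
        """(1440,) scheduled push count per minute."""
        pushes = np.zeros(MINUTES_PER_DAY, dtype=int)
        for bout in self.bouts:
            if bout.propulsion:
                pushes[
                    bout.start_minute : bout.start_minute + bout.duration_minutes
                ] = bout.pushes_per_minute
        return pushes

    def scheduled_rotations(self) -> np.ndarray:
        rotations = np.zeros(MINUTES_PER_DAY, dtype=int)
        for bout in self.bouts:
            if bout.propulsion:
                rotations[
                    bout.start_minute : bout.start_minute + bout.duration_minutes
                ] = bout.rotations_per_minute
        return rotations

    def log_entry(self) -> DailyLogEntry:
        return DailyLogEntry(
            date=self.day_date,
            bedtime_minute=self.bedtime_minute,
            waketime_minute=self.waketime_minute,
            typical_day=self.typical_day,
        )


@dataclass(frozen=True)
class DeviceProfile:
    """Sampling rates and physical parameters of the simulated devices."""

    accel_rate_hz: float = 30.0
    hr_rate_hz: float = 1.0
    gyro_rate_hz: float = 5.0
    wheel_diameter_m: float = 0.6
    battery_life_h: float = 10.5  # smartwatch lasts ~10-11 h per charge
    noise_sd_g: float = 0.0

    def __post_init__(self) -> None:
        if min(self.accel_rate_hz, self.hr_rate_hz, self.gyro_rate_hz) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.battery_life_h <= 0:
            raise ValueError("battery life must be positive")
        if self.wheel_diameter_m <= 0:
            raise ValueError("wheel diameter must be positive")
        if self.noise_sd_g < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class ScheduleParams:
    """Intensity mix and propulsion behavior of the simulated person."""

    proportions: tuple[float, float, float] = (0.7, 0.2, 0.1)  # sed, light, mvpa
    propulsion_prob: float = 0.5  # chance a non-sedentary bout involves pushing
    pushes_per_minute: tuple[int, int] = (8, 20)
    rotations_per_minute: tuple[int, int] = (20, 50)
    bout_minutes: tuple[int, int] = (5, 30)
    waketime_minute: int = 7 * 60
    bedtime_minute: int = 23 * 60
    typical_day_prob: float = 0.9

    def __post_init__(self) -> None:
        p = self.proportions
        if len(p) != 3 or any(x < 0 for x in p):
            raise ValueError("proportions must be 3 non-negative numbers")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("intensity proportions must sum to 1")
        if self.bout_minutes[0] < 1 or self.bout_minutes[0] > self.bout_minutes[1]:
            raise ValueError("invalid bout duration range")
        if not 0 <= self.typical_day_prob <= 1 or not 0 <= self.propulsion_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.waketime_minute < self.bedtime_minute <= MINUTES_PER_DAY:
            raise ValueError("need 0 <= waketime < bedtime <= 1440")


def generate_schedule(
    params: ScheduleParams,
    n_days: int,
    seed: int,
    participant_id: str = "sim01",
    start_date: dt.date = dt.date(2021, 3, 1),
) -> list[ActivitySchedule]:
    """Draw ``n_days`` ground-truth activity schedules, reproducibly.

    Bout durations tile the awake window; each bout's intensity is an
    independent draw from ``params.proportions``.  Propulsion is only
    attached to non-sedentary bouts so that push bursts cannot lift a
    scheduled sedentary minute out of its intensity band.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    schedules = []
    for day in range(n_days):
        bouts: list[Bout] = []
        cursor = params.waketime_minute
        while cursor < params.bedtime_minute:
            lo, hi = params.bout_minutes
            duration = min(int(rng.integers(lo, hi + 1)), params.bedtime_minute - cursor)
            intensity = _INTENSITIES[rng.choice(3, p=params.proportions)]
            propulsion = (
                intensity != Intensity.SEDENTARY
                and rng.random() < params.propulsion_prob
            )
            bouts.append(
                Bout(
                    start_minute=cursor,
                    duration_minutes=duration,
                    intensity=intensity,
                    propulsion=propulsion,
                    pushes_per_minute=(
                        int(rng.integers(*params.pushes_per_minute)) if propulsion else 0
                    ),
                    rotations_per_minute=(
                        int(rng.integers(*params.rotations_per_minute))
                        if propulsion
                        else 0
                    ),
                )
            )
            cursor += duration
        schedules.append(
            ActivitySchedule(
                participant_id=participant_id,
                day_date=start_date + dt.timedelta(days=day),
                waketime_minute=params.waketime_minute,
                bedtime_minute=params.bedtime_minute,
                bouts=bouts,
                typical_day=bool(rng.random() < params.typical_day_prob),
            )
        )
    return schedules


# --- accelerometer rendering -------------------------------------------------

_CYCLES_PER_MINUTE = 12  # slow 0.2 Hz body-movement carrier
_PUSH_DURATION_S = 0.4
_PUSH_AMPLITUDE_G = 0.5
_HR_MEANS = {Intensity.SEDENTARY: 68.0, Intensity.LIGHT: 85.0, Intensity.MVPA: 110.0}


def _mad0(x: np.ndarray) -> float:
    return float(np.mean(np.abs(x - x.mean())))


def _push_train(n_samples: int, n_pushes: int, rate_hz: float) -> np.ndarray:
    """Evenly spaced half-sine bursts over one minute."""
    signal = np.zeros(n_samples)
    if n_pushes <= 0:
        return signal
    burst_len = max(int(round(_PUSH_DURATION_S * rate_hz)), 2)
    burst = _PUSH_AMPLITUDE_G * np.sin(np.linspace(0.0, np.pi, burst_len))
    spacing = n_samples / n_pushes
    for k in range(n_pushes):
        start = int(round(k * spacing))
        stop = min(start + burst_len, n_samples)
        signal[start:stop] += burst[: stop - start]
    return signal


def _solve_amplitude(target_mad: float, carrier: np.ndarray, pushes: np.ndarray) -> float:
    """Carrier amplitude such that MAD(carrier * a + pushes) hits the target.

    The push train alone sets a floor on the attainable MAD; below it the
    amplitude is clamped to 0.
    """
    if not pushes.any():
        return target_mad / _mad0(carrier)
    if _mad0(pushes) >= target_mad:
        return 0.0
    lo, hi = 0.0, target_mad / _mad0(carrier) + target_mad
    while _mad0(carrier * hi + pushes) < target_mad:
        hi *= 2.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _mad0(carrier * mid + pushes) < target_mad:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _target_mad(intensity: Intensity, thresholds: ThresholdConfig, rng) -> float:
    ceiling, floor = thresholds.sedentary_ceiling_g, thresholds.mvpa_floor_g
    if intensity == Intensity.SEDENTARY:
        return float(rng.uniform(0.1, 0.5)) * ceiling
    if intensity == Intensity.LIGHT:
        lo = min(1.5 * ceiling, 0.5 * (ceiling + floor))
        return float(rng.uniform(lo, 0.8 * floor))
    return float(rng.uniform(1.4, 2.5)) * floor


def render_streams(
    schedule: ActivitySchedule,
    device: DeviceProfile = DeviceProfile(),
    seed: int = 0,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> SensorStreams:
    """Render one scheduled day into raw sensor streams.

    Watch streams (accelerometer, heart rate) run from waketime until
    battery death at ``waketime + battery_life`` or bedtime, whichever is
    first; the wheel stream runs for every scheduled propulsion minute.
    """
    rng = np.random.default_rng(seed)
    n_acc = int(round(device.accel_rate_hz * 60))
    n_hr = int(round(device.hr_rate_hz * 60))
    n_gyro = int(round(device.gyro_rate_hz * 60))
    carrier = np.sin(2 * np.pi * _CYCLES_PER_MINUTE * np.arange(n_acc) / n_acc)

    death_minute = schedule.waketime_minute + int(device.battery_life_h * 60)
    watch_end = min(schedule.bedtime_minute, death_minute)

    labels = schedule.minute_labels()
    pushes = schedule.scheduled_pushes()
    rotations = schedule.scheduled_rotations()

    accel_t, accel_parts = [], []
    hr_t, hr_parts = [], []
    wheel_t, wheel_parts = [], []
    hr_state = _HR_MEANS[Intensity.SEDENTARY]

    for minute in range(schedule.waketime_minute, schedule.bedtime_minute):
        intensity = Intensity(labels[minute])
        if minute < watch_end:
            push_sig = _push_train(n_acc, int(pushes[minute]), device.accel_rate_hz)
            amp = _solve_amplitude(_target_mad(intensity, thresholds, rng), carrier, push_sig)
            az = 1.0 + amp * carrier + push_sig
            xyz = np.zeros((n_acc, 3))
            xyz[:, 2] = az
            if device.noise_sd_g > 0:
                xyz += rng.normal(0.0, device.noise_sd_g, size=xyz.shape)
            accel_t.append(minute * 60.0 + np.arange(n_acc) / device.accel_rate_hz)
            accel_parts.append(xyz)

            mu = _HR_MEANS[intensity]
            bpm = np.empty(n_hr)
            for i in range(n_hr):
                hr_state = mu + 0.95 * (hr_state - mu) + rng.normal(0.0, 1.5)
                bpm[i] = hr_state
            hr_t.append(minute * 60.0 + np.arange(n_hr) / device.hr_rate_hz)
            hr_parts.append(bpm)

        if rotations[minute] > 0:
            counts = np.full(n_gyro, rotations[minute] // n_gyro, dtype=float)
            remainder = int(rotations[minute] % n_gyro)
            if remainder:
                counts[np.linspace(0, n_gyro - 1, remainder).astype(int)] += 1
            wheel_t.append(minute * 60.0 + np.arange(n_gyro) / device.gyro_rate_hz)
            wheel_parts.append(counts)

    from .stream_ingest import _gaps_from_minutes  # shared gap convention

    accel_t_arr = np.concatenate(accel_t) if accel_t else np.empty(0)
    return SensorStreams(
        day_date=schedule.day_date,
        accel_t=accel_t_arr,
        accel_xyz=np.concatenate(accel_parts) if accel_parts else np.empty((0, 3)),
        hr_t=np.concatenate(hr_t) if hr_t else np.empty(0),
        hr_bpm=np.concatenate(hr_parts) if hr_parts else np.empty(0),
        wheel_t=np.concatenate(wheel_t) if wheel_t else np.empty(0),
        wheel_rotations=np.concatenate(wheel_parts) if wheel_parts else np.empty(0),
        gaps=_gaps_from_minutes(accel_t_arr),
    )


def generate_table2_like_cohort(
    n: int,
    effect: float,
    seed: int,
    baseline_mean: float = 26.4,
    baseline_sd: float = 16.9,
    noise_sd: float = 12.0,
) -> list[tuple[PhaseSummary, PhaseSummary]]:
    """Paired pre/post phase summaries for calibration of the group tests.

    Baseline daily exercise time is Normal(baseline_mean, baseline_sd)
    clipped at 0.1 min; intervention = baseline + effect + Normal(0,
    noise_sd).  With ``effect = 0`` the paired differences are symmetric
    about zero, so the cohort is a proper null for type-I checks.
    """
    if n < 5:
        raise ValueError("n must be at least 5 (signed-rank test degenerate below)")
    rng = np.random.default_rng(seed)
    baseline_ex = np.clip(rng.normal(baseline_mean, baseline_sd, size=n), 0.1, None)
    intervention_ex = baseline_ex + effect + rng.normal(0.0, noise_sd, size=n)
    baseline_breaks = np.clip(rng.normal(16.9, 3.7, size=n), 0.0, None)
    intervention_breaks = np.clip(baseline_breaks + rng.normal(0.0, 3.0, size=n), 0.0, None)
    baseline_dist = np.clip(rng.normal(0.8, 0.6, size=n), 0.05, None)
    intervention_dist = np.clip(baseline_dist + rng.normal(0.0, 0.4, size=n), 0.05, None)
    n_days = rng.integers(3, 8, size=(n, 2))

    cohort = []
    for i in range(n):
        pid = f"{i + 1:02d}"
        cohort.append(
            (
                PhaseSummary(
                    participant_id=pid,
                    phase="baseline",
                    exercise_time_min=float(baseline_ex[i]),
                    sedentary_breaks=float(baseline_breaks[i]),
                    distance_miles=float(baseline_dist[i]),
                    n_valid_days=int(n_days[i, 0]),
                ),
                PhaseSummary(
                    participant_id=pid,
                    phase="intervention",
                    exercise_time_min=float(intervention_ex[i]),
                    sedentary_breaks=float(intervention_breaks[i]),
                    distance_miles=float(intervention_dist[i]),
                    n_valid_days=int(n_days[i, 1]),
                ),
            )
        )
    return cohort


def write_simulation(
    schedules: list[ActivitySchedule],
    out_dir: str | Path,
    device: DeviceProfile = DeviceProfile(),
    seed: int = 0,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> Path:
    """Render and write a multi-day simulation in the ingest CSV dialect.

    Layout: ``<out>/day_<date>/{accel,hr,wheel}.csv`` plus ``daily_log.csv``
    and a ``ground_truth.csv`` with scheduled per-minute labels and pushes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for i, schedule in enumerate(schedules):
        streams = render_streams(schedule, device, seed=seed + i, thresholds=thresholds)
        write_streams(streams, out_dir / f"day_{schedule.day_date.isoformat()}")
        labels = schedule.minute_labels()
        pushes = schedule.scheduled_pushes()
        for minute in range(MINUTES_PER_DAY):
            truth_rows.append(
                (schedule.day_date.isoformat(), minute, int(labels[minute]), int(pushes[minute]))
            )
    write_daily_log([s.log_entry() for s in schedules], out_dir / "daily_log.csv")
    import csv

    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "minute", "label", "pushes"])
        writer.writerows(truth_rows)
    return out_dir
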