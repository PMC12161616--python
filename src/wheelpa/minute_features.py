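"""Per-minute feature extraction: signal MAD, push counts, distance, energy.

The per-minute mean absolute deviation (MAD) of the acceleration vector
magnitude is the basis of all intensity classification downstream.  The push
detector and the energy model are explicit, configurable stand-ins: the
deployed algorithms they replace are proprietary/unpublished, so defaults
here are documented placeholders, not validated coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .stream_ingest import MINUTES_PER_DAY, MinuteBins

__all__ = [
    "MinuteRecord",
    "PushDetectorConfig",
    "EnergyModel",
    "Demographics",
    "mad",
    "count_pushes",
    "rotations_to_distance",
    "estimate_energy",
    "compute_minute_records",
    "HR_FORWARD_FILL_MAX_MINUTES",
]

HR_FORWARD_FILL_MAX_MINUTES = 5


@dataclass(frozen=True)
class PushDetectorConfig:
    """Peak-based propulsion stroke detector parameters.

    The detrend window removes gravity and slow body movement; peaks of the
    residual magnitude above ``min_prominence`` separated by at least the
    refractory interval are counted as pushes.
    """

    sample_rate_hz: float = 30.0
    detrend_window_s: float = 1.0
    min_prominence_g: float = 0.2
    refractory_s: float = 0.5

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.detrend_window_s <= 0:
            raise ValueError("sample rate and detrend window must be positive")
        if self.min_prominence_g <= 0 or self.refractory_s <= 0:
            raise ValueError("prominence and refractory interval must be positive")


@dataclass(frozen=True)
class EnergyModel:
    """Placeholder linear energy model — NOT validated.

    kcal/min = basal_kcal_per_kg_min * mass
             + mad_coef_kcal_per_g_kg * MAD * mass
             + hr_coef_kcal_per_bpm * max(hr - rest_hr_bpm, 0)

    The interface is the contract; coefficients are ship-as-config
    placeholders standing in for an unpublished device-specific model.
    """

    basal_kcal_per_kg_min: float = 1.0 / 60.0  # ~1 kcal/kg/h resting
    mad_coef_kcal_per_g_kg: float = 0.09
    hr_coef_kcal_per_bpm: float = 0.005
    rest_hr_bpm: float = 65.0

    def __post_init__(self) -> None:
        if self.basal_kcal_per_kg_min < 0:
            raise ValueError("basal rate must be non-negative")


@dataclass(frozen=True)
class Demographics:
    mass_kg: float
    height_cm: float | None = None
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.mass_kg is None or not self.mass_kg > 0:
            raise ValueError("missing or invalid demographics field: mass_kg")


@dataclass
class MinuteRecord:
    """One minute's derived features; ``mad`` is None for null minutes."""

    minute_index: int
    mad: float | None
    pushes: int
    rotations: float
    distance_m: float
    hr_last: float | None
    energy_kcal: float

    def __post_init__(self) -> None:
        if not 0 <= self.minute_index < MINUTES_PER_DAY:
            raise ValueError("minute_index out of range")
        if self.mad is not None and self.mad < 0:
            raise ValueError("mad must be non-negative")
        if self.pushes < 0 or self.rotations < 0 or self.distance_m < 0:
            raise ValueError("counts and distance must be non-negative")


def vector_magnitude(accel_xyz: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(accel_xyz, dtype=float).reshape(-1, 3), axis=1)


def mad(accel_minute: np.ndarray) -> float:
    """Mean absolute deviation of the acceleration vector magnitude, in g.

    MAD = (1/N) * sum_i |r_i - rbar| with r_i = sqrt(ax^2 + ay^2 + az^2).
    """
    r = vector_magnitude(accel_minute)
    if r.size == 0:
        raise ValueError("mad requires at least one sample; null minutes carry None")
    return float(np.mean(np.abs(r - r.mean())))


def count_pushes(
    accel_minute: np.ndarray, cfg: PushDetectorConfig = PushDetectorConfig()
) -> int:
    """Count propulsion strokes in one minute of triaxial acceleration.

    Deterministic for a fixed config: moving-average-detrended vector
    magnitude, peak detection with a minimum prominence, and a refractory
    interval so that burst pairs closer than ``refractory_s`` merge into one.
    """
    r = vector_magnitude(accel_minute)
    if r.size == 0:
        raise ValueError("count_pushes requires a non-null minute")
    window = max(int(round(cfg.detrend_window_s * cfg.sample_rate_hz)), 1)
    if r.size < 2 * window:
        return 0
    # 'nearest' edge handling keeps the gravity offset out of the residual
    # at the minute boundaries.
    baseline = uniform_filter1d(r, size=window, mode="nearest")
    residual = r - baseline
    distance = max(int(round(cfg.refractory_s * cfg.sample_rate_hz)), 1)
    peaks, _ = find_peaks(
        residual, prominence=cfg.min_prominence_g, distance=distance
    )
    return int(len(peaks))


def rotations_to_distance(rotations: float, wheel_diameter_m: float) -> float:
    """Distance in meters from wheel rotations: rotations * pi * diameter."""
    if wheel_diameter_m <= 0:
        raise ValueError("wheel diameter must be positive (configuration error)")
    if rotations < 0:
        raise ValueError("rotations must be non-negative")
    return float(rotations) * np.pi * float(wheel_diameter_m)


def estimate_energy(
    mad_g: float | None,
    hr_bpm: float | None,
    person: Demographics,
    model: EnergyModel = EnergyModel(),
) -> float:
    """Per-minute kcal from the pluggable energy model; 0 for null minutes."""
    if mad_g is None:
        return 0.0
    kcal = model.basal_kcal_per_kg_min * person.mass_kg
    kcal += model.mad_coef_kcal_per_g_kg * mad_g * person.mass_kg
    if hr_bpm is not None:
        kcal += model.hr_coef_kcal_per_bpm * max(hr_bpm - model.rest_hr_bpm, 0.0)
    return max(kcal, 0.0)


def compute_minute_records(
    bins: MinuteBins,
    wheel_diameter_m: float,
    person: Demographics,
    push_cfg: PushDetectorConfig = PushDetectorConfig(),
    energy_model: EnergyModel = EnergyModel(),
) -> list[MinuteRecord]:
    """Derive the full per-minute feature table for one day.

    Pushes are only counted in minutes with nonzero wheel rotations (the
    wheel sensor gates the wrist detector).  ``hr_last`` is the latest
    heart-rate sample of the minute, forward-filled across heart-rate-free
    minutes for at most ``HR_FORWARD_FILL_MAX_MINUTES`` minutes.
    """
    records: list[MinuteRecord] = []
    last_hr: float | None = None
    minutes_since_hr = HR_FORWARD_FILL_MAX_MINUTES + 1
    for minute in range(MINUTES_PER_DAY):
        block = bins.accel[minute]
        hr_samples = bins.hr[minute]
        if len(hr_samples):
            last_hr = float(hr_samples[-1])
            minutes_since_hr = 0
        else:
            minutes_since_hr += 1
        hr_last = last_hr if minutes_since_hr <= HR_FORWARD_FILL_MAX_MINUTES else None
        rotations = float(bins.rotations[minute])
        distance = rotations_to_distance(rotations, wheel_diameter_m)
        if block is None:
            records.append(
                MinuteRecord(
                    minute_index=minute,
                    mad=None,
                    pushes=0,
                    rotations=rotations,
                    distance_m=distance,
                    hr_last=hr_last,
                    energy_kcal=0.0,
                )
            )
            continue
        minute_mad = mad(block)
        pushes = count_pushes(block, push_cfg) if rotations > 0 else 0
        records.append(
            MinuteRecord(
                minute_index=minute,
                mad=minute_mad,
                pushes=pushes,
                rotations=rotations,
                distance_m=distance,
                hr_last=hr_last,
                energy_kcal=estimate_energy(minute_mad, hr_last, person, energy_model),
            )
        )
    return records
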