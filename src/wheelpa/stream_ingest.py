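"""Reading and minute-gridding of multi-rate wearable sensor streams.

Three plain-text CSV dialects are supported, one file per stream per day:

* ``accel.csv`` — ``iso_timestamp,ax,ay,az`` (triaxial acceleration, g units)
* ``hr.csv``    — ``iso_timestamp,bpm``
* ``wheel.csv`` — ``iso_timestamp,rotations`` (wheel rotations per sample window)

plus a daily log CSV (``date,bedtime,waketime,typical_day``) with clock times
as ``HH:MM``.

All samples of a day are aligned onto a 1440-slot minute grid anchored at
local midnight; minutes are half-open ``[t, t + 60 s)``.  A minute is *null*
exactly when it holds no accelerometer sample.  Wear/connection coverage is
the fraction of non-null minutes over the full 24 h grid (1440 minutes) by
default — a day that reaches the 30 % coverage floor therefore carries about
7.2 h of watch data.  Pass an explicit ``denominator`` to ``coverage`` to
measure against awake time instead.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorStreams",
    "MinuteBins",
    "DailyLogEntry",
    "read_streams",
    "write_streams",
    "read_daily_log",
    "write_daily_log",
    "bin_minutes",
    "coverage",
    "MINUTES_PER_DAY",
]

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
SECONDS_PER_DAY = 86400.0

ACCEL_COLUMNS = ["iso_timestamp", "ax", "ay", "az"]
HR_COLUMNS = ["iso_timestamp", "bpm"]
WHEEL_COLUMNS = ["iso_timestamp", "rotations"]
DAILY_LOG_COLUMNS = ["date", "bedtime", "waketime", "typical_day"]


@dataclass
class SensorStreams:
    """One day of raw multi-rate sensor data on a common clock.

    Timestamps are seconds since local midnight of ``day_date``.  ``gaps``
    lists half-open ``[start, end)`` second intervals holding no watch
    (accelerometer) data; they are inferred from the minute grid.
    """

    day_date: dt.date
    accel_t: np.ndarray  # (n,) float seconds
    accel_xyz: np.ndarray  # (n, 3) float g
    hr_t: np.ndarray
    hr_bpm: np.ndarray
    wheel_t: np.ndarray
    wheel_rotations: np.ndarray
    gaps: list[tuple[float, float]] = field(default_factory=list)
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        self.accel_t = np.asarray(self.accel_t, dtype=float)
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float).reshape(-1, 3)
        self.hr_t = np.asarray(self.hr_t, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.wheel_t = np.asarray(self.wheel_t, dtype=float)
        self.wheel_rotations = np.asarray(self.wheel_rotations, dtype=float)
        for name, t in (
            ("accel", self.accel_t),
            ("hr", self.hr_t),
            ("wheel", self.wheel_t),
        ):
            if t.size and (np.any(np.diff(t) <= 0)):
                row = int(np.argmax(np.diff(t) <= 0)) + 1
                raise ValueError(
                    f"{name} timestamps not strictly increasing at row {row}"
                )
            if t.size and (t[0] < 0 or t[-1] >= SECONDS_PER_DAY):
                raise ValueError(f"{name} samples fall outside {self.day_date}")
        if self.gaps:
            starts = [g[0] for g in self.gaps]
            if sorted(starts) != starts:
                raise ValueError("gap intervals must be sorted and disjoint")


@dataclass
class DailyLogEntry:
    """One self-report row: sleep window and typical-day confirmation."""

    date: dt.date
    bedtime_minute: int  # clock minute 0..1439 (or 1440 for midnight-end)
    waketime_minute: int
    typical_day: bool

    def __post_init__(self) -> None:
        if not 0 <= self.waketime_minute < MINUTES_PER_DAY:
            raise ValueError("waketime outside the day")
        if not self.waketime_minute < self.bedtime_minute <= MINUTES_PER_DAY:
            raise ValueError("bedtime must follow waketime within the day")


@dataclass
class MinuteBins:
    """Per-day minute grid: exactly 1440 slots of grouped raw samples.

    ``accel[i]`` is the ``(n, 3)`` sample block of minute *i* or ``None``
    when the minute holds no accelerometer sample (the null flag).
    """

    day_date: dt.date
    accel: list[np.ndarray | None]
    hr: list[np.ndarray]
    rotations: np.ndarray  # (1440,) summed per minute

    def __post_init__(self) -> None:
        if len(self.accel) != MINUTES_PER_DAY or len(self.hr) != MINUTES_PER_DAY:
            raise ValueError("minute grid must have exactly 1440 slots")
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.shape != (MINUTES_PER_DAY,):
            raise ValueError("rotations must have exactly 1440 slots")

    @property
    def null_mask(self) -> np.ndarray:
        """Boolean (1440,) array: True where the minute has no accel data."""
        return np.array([a is None for a in self.accel])


def _seconds_since_midnight(ts: pd.Series, day_date: dt.date) -> np.ndarray:
    parsed = pd.to_datetime(ts, format="ISO8601")
    midnight = pd.Timestamp(day_date)
    return (parsed - midnight).dt.total_seconds().to_numpy()


def _read_csv_strict_header(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: unparseable header {list(df.columns)!r}; expected {columns}"
        )
    return df


def _parse_stream(
    path: Path, columns: list[str], day_date: dt.date
) -> tuple[np.ndarray, np.ndarray, int]:
    """Parse one stream file; returns (t_seconds, values, n_skipped)."""
    df = _read_csv_strict_header(path, columns)
    value_cols = columns[1:]
    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    ts = pd.to_datetime(df[columns[0]], format="ISO8601", errors="coerce")
    bad = values.isna().any(axis=1) | ts.isna()
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    ts, values = ts[~bad], values[~bad]
    midnight = pd.Timestamp(day_date)
    t = (ts - midnight).dt.total_seconds().to_numpy()
    order = np.diff(t) <= 0 if t.size else np.array([], dtype=bool)
    if np.any(order):
        row = int(np.argmax(order)) + 2  # 1-based, plus header
        raise ValueError(f"{path}: out-of-order timestamp at data row {row}")
    return t, values.to_numpy(dtype=float), n_skipped


def _infer_day_date(paths: list[Path]) -> dt.date:
    for path in paths:
        df = pd.read_csv(path, nrows=1)
        if len(df):
            return pd.to_datetime(df.iloc[0, 0], format="ISO8601").date()
    raise ValueError("cannot infer day date: all stream files are empty")


def _gaps_from_minutes(accel_t: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of accel-free minutes, as [start, end) second intervals."""
    has_data = np.zeros(MINUTES_PER_DAY, dtype=bool)
    if accel_t.size:
        has_data[np.unique((accel_t // 60).astype(int))] = True
    gaps: list[tuple[float, float]] = []
    start = None
    for minute in range(MINUTES_PER_DAY):
        if not has_data[minute] and start is None:
            start = minute
        elif has_data[minute] and start is not None:
            gaps.append((start * 60.0, minute * 60.0))
            start = None
    if start is not None:
        gaps.append((start * 60.0, SECONDS_PER_DAY))
    return gaps


def read_streams(
    accel_path: str | Path,
    hr_path: str | Path,
    wheel_path: str | Path,
    day_date: dt.date | None = None,
) -> SensorStreams:
    """Read one day's accelerometer / heart-rate / wheel CSV files.

    Malformed data rows (non-numeric values, unparseable timestamps) are
    skipped and counted in ``n_skipped_rows``; a wrong header or an
    out-of-order timestamp is a hard error.  Gaps are inferred as maximal
    runs of minutes without accelerometer samples.
    """
    accel_path, hr_path, wheel_path = Path(accel_path), Path(hr_path), Path(wheel_path)
    if day_date is None:
        day_date = _infer_day_date([accel_path, hr_path, wheel_path])
    accel_t, accel_xyz, skipped_a = _parse_stream(accel_path, ACCEL_COLUMNS, day_date)
    hr_t, hr_vals, skipped_h = _parse_stream(hr_path, HR_COLUMNS, day_date)
    wheel_t, wheel_vals, skipped_w = _parse_stream(wheel_path, WHEEL_COLUMNS, day_date)
    return SensorStreams(
        day_date=day_date,
        accel_t=accel_t,
        accel_xyz=accel_xyz,
        hr_t=hr_t,
        hr_bpm=hr_vals.ravel(),
        wheel_t=wheel_t,
        wheel_rotations=wheel_vals.ravel(),
        gaps=_gaps_from_minutes(accel_t),
        n_skipped_rows=skipped_a + skipped_h + skipped_w,
    )


def _iso(day_date: dt.date, t_seconds: np.ndarray) -> pd.Series:
    base = pd.Timestamp(day_date)
    return pd.Series(base + pd.to_timedelta(t_seconds, unit="s")).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    )


def write_streams(streams: SensorStreams, out_dir: str | Path) -> dict[str, Path]:
    """Write the three stream CSVs for one day; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "accel": out_dir / "accel.csv",
        "hr": out_dir / "hr.csv",
        "wheel": out_dir / "wheel.csv",
    }
    pd.DataFrame(
        {
            "iso_timestamp": _iso(streams.day_date, streams.accel_t),
            "ax": streams.accel_xyz[:, 0],
            "ay": streams.accel_xyz[:, 1],
            "az": streams.accel_xyz[:, 2],
        }
    ).to_csv(paths["accel"], index=False)
    pd.DataFrame(
        {"iso_timestamp": _iso(streams.day_date, streams.hr_t), "bpm": streams.hr_bpm}
    ).to_csv(paths["hr"], index=False)
    pd.DataFrame(
        {
            "iso_timestamp": _iso(streams.day_date, streams.wheel_t),
            "rotations": streams.wheel_rotations,
        }
    ).to_csv(paths["wheel"], index=False)
    return paths


def _clock(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


def write_daily_log(entries: list[DailyLogEntry], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "date": [e.date.isoformat() for e in entries],
            "bedtime": [_clock(e.bedtime_minute % MINUTES_PER_DAY) for e in entries],
            "waketime": [_clock(e.waketime_minute) for e in entries],
            "typical_day": [int(e.typical_day) for e in entries],
        }
    ).to_csv(path, index=False)
    return path


def read_daily_log(path: str | Path) -> dict[dt.date, DailyLogEntry]:
    """Read the daily log; returns entries keyed by date."""
    df = _read_csv_strict_header(Path(path), DAILY_LOG_COLUMNS)
    entries: dict[dt.date, DailyLogEntry] = {}
    for _, row in df.iterrows():
        date = dt.date.fromisoformat(row["date"])
        bed_h, bed_m = (int(x) for x in row["bedtime"].split(":"))
        wake_h, wake_m = (int(x) for x in row["waketime"].split(":"))
        bedtime = bed_h * 60 + bed_m
        if bedtime == 0:
            bedtime = MINUTES_PER_DAY  # midnight bedtime ends the day
        entries[date] = DailyLogEntry(
            date=date,
            bedtime_minute=bedtime,
            waketime_minute=wake_h * 60 + wake_m,
            typical_day=bool(int(row["typical_day"])),
        )
    return entries


def bin_minutes(streams: SensorStreams) -> MinuteBins:
    """Assign samples to half-open minute intervals ``[t, t + 60 s)``.

    A sample stamped exactly on a minute boundary belongs to the later
    minute.  Rotation counts are summed per minute.
    """
    edges = np.arange(MINUTES_PER_DAY + 1) * 60.0

    def split(t: np.ndarray, values: np.ndarray) -> list[np.ndarray]:
        idx = np.searchsorted(t, edges)
        return [values[idx[m] : idx[m + 1]] for m in range(MINUTES_PER_DAY)]

    accel_blocks = split(streams.accel_t, streams.accel_xyz)
    accel = [block if len(block) else None for block in accel_blocks]
    hr = split(streams.hr_t, streams.hr_bpm)
    rotations = np.zeros(MINUTES_PER_DAY)
    if streams.wheel_t.size:
        minute_of = (streams.wheel_t // 60).astype(int)
        np.add.at(rotations, minute_of, streams.wheel_rotations)
    return MinuteBins(
        day_date=streams.day_date, accel=accel, hr=hr, rotations=rotations
    )


def coverage(bins: MinuteBins, denominator: int = MINUTES_PER_DAY) -> float:
    """Fraction of minutes holding accelerometer data of nonzero magnitude.

    The default denominator is the full 24 h grid (1440 minutes), so 30 %
    coverage corresponds to about 7.2 h of watch wear.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    n_good = 0
    for block in bins.accel:
        if block is not None and np.any(np.linalg.norm(block, axis=1) > 0):
            n_good += 1
    return n_good / denominator
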