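"""Pre-post study analysis of daily physical-activity summaries.

Implements the full analysis chain: valid-day filtering (coverage floor,
abnormal-data checks, typical-day confirmation), per-phase daily means,
rounded percent change with a ±10 % "considerable change" rule, the
Wilcoxon signed-rank test (normal approximation, tie-corrected variance, no
continuity correction, effect size r = Z / sqrt(n)) and the paired t test,
plus a per-participant report table.

A 16-participant pre/post cohort fixture (four variables: daily exercise
time, sedentary breaks, travel distance, and an exercise self-efficacy
score) ships with the package; all of its group statistics are recomputable
from the per-participant one-decimal values.

Notes on reporting conventions:

* both one- and two-sided p-values are always attached to ``TestResult``;
* the SD of the paired differences (``sd_diff``) is reported alongside
  Cohen's d_z — some reports label the raw difference SD as "d";
* group medians of fixture variables are computed on the one-decimal
  per-participant values as stored.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .daily_metrics import DayRecord
from .stream_ingest import DailyLogEntry

__all__ = [
    "PhaseSummary",
    "ChangeRecord",
    "TestResult",
    "StudyResult",
    "valid_day",
    "phase_means",
    "percent_change",
    "classify_change",
    "wilcoxon_signed_rank",
    "paired_t",
    "summarize_study",
    "power_sample_size",
    "load_cohort_fixture",
    "COVERAGE_FLOOR",
    "CONSIDERABLE_CHANGE_PCT",
    "FIXTURE_VARIABLES",
]

logger = logging.getLogger(__name__)

COVERAGE_FLOOR = 0.30
CONSIDERABLE_CHANGE_PCT = 10

CONSIDERABLE_INCREASE = "considerable_increase"
CONSIDERABLE_DECREASE = "considerable_decrease"
NO_CONSIDERABLE_CHANGE = "no_considerable_change"

FIXTURE_VARIABLES = ("exercise_time", "sedentary_breaks", "distance", "eses")


@dataclass
class PhaseSummary:
    """Per-participant daily means over the valid days of one phase."""

    participant_id: str
    phase: str  # "baseline" | "intervention"
    exercise_time_min: float
    sedentary_breaks: float
    distance_miles: float
    n_valid_days: int

    def __post_init__(self) -> None:
        if self.phase not in ("baseline", "intervention"):
            raise ValueError("phase must be 'baseline' or 'intervention'")
        if self.n_valid_days < 1:
            raise ValueError("a phase summary requires at least one valid day")
        for value in (self.exercise_time_min, self.sedentary_breaks, self.distance_miles):
            if not math.isfinite(value):
                raise ValueError("phase means must be finite")


@dataclass(frozen=True)
class ChangeRecord:
    participant_id: str
    variable: str
    pct_change: int | None
    category: str | None


@dataclass
class TestResult:
    """Outcome of one paired group test."""

    test: str  # "wilcoxon" | "paired_t"
    statistic: float  # Z for wilcoxon, t for paired_t
    n: int
    p_two_sided: float
    p_one_sided: float
    df: int | None = None
    effect_size_r: float | None = None  # Z / sqrt(n)
    mean_diff: float | None = None
    sd_diff: float | None = None
    cohens_dz: float | None = None
    w_plus: float | None = None
    w_minus: float | None = None


@dataclass
class StudyResult:
    """Group-level report: per-participant table, tests, change categories."""

    table: pd.DataFrame
    means: dict[str, dict[str, float]]
    sds: dict[str, dict[str, float]]
    medians: dict[str, dict[str, float]]
    tests: dict[str, TestResult]
    change_records: list[ChangeRecord]
    change_counts: dict[str, int]


def valid_day(
    day: DayRecord,
    log_entry: DailyLogEntry | None,
    min_coverage: float = COVERAGE_FLOOR,
) -> bool:
    """Apply the three valid-day criteria to one day.

    (1) accelerometer coverage at or above ``min_coverage``; (2) no abnormal
    sensor data — nonzero pushes with zero travel distance, or a silent
    wheel stream on a day with non-sedentary activity; (3) the participant
    confirmed a typical day in the daily log.  A missing log entry excludes
    the day with a warning.
    """
    if log_entry is None:
        logger.warning("day %s excluded: no daily-log entry", day.day_date)
        return False
    if day.coverage < min_coverage:
        return False
    if day.push_total > 0 and day.distance_m == 0:
        return False  # abnormal: pushing registered but no travel distance
    if day.rotations_total == 0 and day.n_nonsedentary_minutes > 0:
        return False  # abnormal: active day with an all-zero wheel stream
    return bool(log_entry.typical_day)


def phase_means(
    days: list[DayRecord], participant_id: str, phase: str
) -> PhaseSummary:
    """Arithmetic daily means of the PA variables over one phase's valid days."""
    if not days:
        raise ValueError(
            f"participant {participant_id} has no valid {phase} days; "
            "excluded from group tests"
        )
    return PhaseSummary(
        participant_id=participant_id,
        phase=phase,
        exercise_time_min=float(np.mean([d.mvpa_minutes for d in days])),
        sedentary_breaks=float(np.mean([d.sedentary_breaks for d in days])),
        distance_miles=float(np.mean([d.distance_miles for d in days])),
        n_valid_days=len(days),
    )


def percent_change(baseline: float, intervention: float) -> int | None:
    """Rounded integer percent change, half away from zero; None if undefined."""
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    if baseline == 0:
        return None
    raw = 100.0 * (intervention - baseline) / baseline
    # snap float noise (e.g. -42.4999999999999) before rounding half away
    # from zero, matching decimal arithmetic on one-decimal inputs
    raw = round(raw, 9)
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw))


def classify_change(pct: int | None) -> str | None:
    """±10 % considerable-change rule; the boundary itself is no change."""
    if pct is None:
        return None
    if pct > CONSIDERABLE_CHANGE_PCT:
        return CONSIDERABLE_INCREASE
    if pct < -CONSIDERABLE_CHANGE_PCT:
        return CONSIDERABLE_DECREASE
    return NO_CONSIDERABLE_CHANGE


def wilcoxon_signed_rank(baseline, intervention) -> TestResult:
    """Wilcoxon signed-rank test on paired values, normal approximation.

    Zero differences are dropped; tied absolute differences take average
    ranks, with the usual tie correction in the variance.  No continuity
    correction is applied.  Z is signed by W+ relative to its null mean, and
    the effect size is r = Z / sqrt(n) with n the pairs entering the test.
    """
    baseline = np.asarray(baseline, dtype=float)
    intervention = np.asarray(intervention, dtype=float)
    if baseline.shape != intervention.shape or baseline.ndim != 1:
        raise ValueError("baseline and intervention must be equal-length vectors")
    diffs = intervention - baseline
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise ValueError("all paired differences are zero; Z undefined (degenerate)")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences for the rank test")
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum())
    ) / 48.0
    if sigma2 <= 0:
        raise ValueError("degenerate variance in signed-rank test")
    z = (w_plus - mu) / math.sqrt(sigma2)
    p_two = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        test="wilcoxon",
        statistic=z,
        n=n,
        p_two_sided=min(p_two, 1.0),
        p_one_sided=float(stats.norm.sf(z)),
        effect_size_r=z / math.sqrt(n),
        w_plus=w_plus,
        w_minus=w_minus,
    )


def paired_t(baseline, intervention) -> TestResult:
    """Paired-sample t test: t = mean(d) / (sd(d) / sqrt(n)), df = n - 1."""
    baseline = np.asarray(baseline, dtype=float)
    intervention = np.asarray(intervention, dtype=float)
    if baseline.shape != intervention.shape or baseline.ndim != 1:
        raise ValueError("baseline and intervention must be equal-length vectors")
    n = baseline.size
    if n < 2:
        raise ValueError("paired t test requires at least 2 pairs")
    diffs = intervention - baseline
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    mean = float(np.mean(diffs))
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    return TestResult(
        test="paired_t",
        statistic=t,
        n=n,
        df=df,
        p_two_sided=2.0 * float(stats.t.sf(abs(t), df)),
        p_one_sided=float(stats.t.sf(t, df)),
        mean_diff=mean,
        sd_diff=sd,
        cohens_dz=mean / sd,
    )


def load_cohort_fixture() -> pd.DataFrame:
    """The packaged 16-participant pre/post cohort, one-decimal values."""
    ref = importlib.resources.files("wheelpa.data").joinpath("prepost_cohort.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"participant_id": str})


def summarize_study(
    cohort: pd.DataFrame, change_variable: str = "exercise_time"
) -> StudyResult:
    """Build the full group report from a pre/post cohort table.

    ``cohort`` needs ``participant_id`` plus ``<var>_baseline`` /
    ``<var>_intervention`` columns for the variables in
    ``FIXTURE_VARIABLES`` (``eses`` optional).  The signed-rank test is run
    on exercise time and sedentary breaks, the paired t on the
    self-efficacy score; the ±10 % rule is applied to ``change_variable``.
    """
    if len(cohort) < 5:
        raise ValueError("need phase summaries for at least 5 participants")
    variables = [
        v
        for v in FIXTURE_VARIABLES
        if f"{v}_baseline" in cohort.columns and f"{v}_intervention" in cohort.columns
    ]
    if change_variable not in variables:
        raise ValueError(f"cohort lacks columns for variable {change_variable!r}")

    table = cohort[["participant_id"]].copy()
    means: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    medians: dict[str, dict[str, float]] = {}
    for var in variables:
        b = cohort[f"{var}_baseline"].to_numpy(dtype=float)
        i = cohort[f"{var}_intervention"].to_numpy(dtype=float)
        table[f"{var}_baseline"] = b
        table[f"{var}_intervention"] = i
        table[f"{var}_pct_change"] = [
            percent_change(bv, iv) for bv, iv in zip(b, i)
        ]
        means[var] = {"baseline": float(b.mean()), "intervention": float(i.mean())}
        sds[var] = {
            "baseline": float(b.std(ddof=1)),
            "intervention": float(i.std(ddof=1)),
        }
        medians[var] = {
            "baseline": float(np.median(b)),
            "intervention": float(np.median(i)),
        }

    tests: dict[str, TestResult] = {}
    for var in ("exercise_time", "sedentary_breaks"):
        if var in variables:
            tests[var] = wilcoxon_signed_rank(
                cohort[f"{var}_baseline"], cohort[f"{var}_intervention"]
            )
    if "eses" in variables:
        tests["eses"] = paired_t(
            cohort["eses_baseline"], cohort["eses_intervention"]
        )

    change_records = [
        ChangeRecord(
            participant_id=str(row["participant_id"]),
            variable=change_variable,
            pct_change=row[f"{change_variable}_pct_change"],
            category=classify_change(row[f"{change_variable}_pct_change"]),
        )
        for _, row in table.iterrows()
    ]
    change_counts = {
        CONSIDERABLE_INCREASE: 0,
        CONSIDERABLE_DECREASE: 0,
        NO_CONSIDERABLE_CHANGE: 0,
    }
    for record in change_records:
        if record.category is not None:
            change_counts[record.category] += 1

    return StudyResult(
        table=table,
        means=means,
        sds=sds,
        medians=medians,
        tests=tests,
        change_records=change_records,
        change_counts=change_counts,
    )


def report_frame(result: StudyResult) -> pd.DataFrame:
    """Report table with a trailing mean (SD) row, one decimal, like the app's export."""
    table = result.table.copy()
    summary: dict[str, object] = {"participant_id": "Mean (SD)"}
    for column in table.columns:
        if column.endswith("_baseline") or column.endswith("_intervention"):
            var, _, phase = column.rpartition("_")
            summary[column] = (
                f"{result.means[var][phase]:.1f} ({result.sds[var][phase]:.1f})"
            )
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)


def _paired_t_power(n: int, effect_d: float, alpha: float, sided: int) -> float:
    df = n - 1
    nc = effect_d * math.sqrt(n)
    crit = stats.t.isf(alpha / sided, df)
    upper = float(stats.nct.sf(crit, df, nc))
    if not math.isfinite(upper):  # scipy underflows at extreme noncentrality
        upper = float(stats.norm.sf(crit - nc))
    if sided == 1:
        return upper
    lower = float(stats.nct.cdf(-crit, df, nc))
    if not math.isfinite(lower):
        lower = 0.0  # negligible opposite tail for positive effects
    return upper + lower


def power_sample_size(
    effect_d: float,
    power: float = 0.8,
    alpha: float = 0.05,
    sided: int = 2,
    max_n: int = 100_000,
) -> int:
    """Smallest n with paired-t power >= target, by noncentral-t iteration."""
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie strictly in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect size must be positive")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    for n in range(2, max_n + 1):
        if _paired_t_power(n, effect_d, alpha, sided) >= power:
            return n
    raise ValueError("no sample size up to max_n reaches the target power")
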