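import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wheelpa import study_analysis as sa
from wheelpa.daily_metrics import DayRecord
from wheelpa.stream_ingest import DailyLogEntry

DAY = dt.date(2021, 3, 1)


def make_day(
    coverage=0.6,
    push_total=500,
    distance_m=1200.0,
    rotations_total=700.0,
    mvpa=20,
    nonsed=120,
):
    return DayRecord(
        day_date=DAY,
        energy_kcal=1500.0,
        distance_m=distance_m,
        mvpa_minutes=mvpa,
        sedentary_breaks=12,
        push_total=push_total,
        rotations_total=rotations_total,
        coverage=coverage,
        n_nonnull_minutes=900,
        n_nonsedentary_minutes=nonsed,
    )


def make_log(typical=True):
    return DailyLogEntry(DAY, bedtime_minute=1380, waketime_minute=420, typical_day=typical)


def exact_wilcoxon_p_two_sided(baseline, intervention, convention="midp"):
    """Enumeration oracle over all 2^n sign assignments.

    ``midp`` (default) counts half of the probability mass tied with the
    observed statistic — the quantity an uncorrected normal approximation
    estimates; ``inclusive`` counts all of it (the conventional exact p,
    which the approximation systematically undershoots at small n).
    """
    diffs = np.asarray(intervention, float) - np.asarray(baseline, float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    mu = n * (n + 1) / 4.0
    observed = abs(ranks[diffs > 0].sum() - mu)
    beyond = ties = 0
    for signs in itertools.product([0, 1], repeat=n):
        dist = abs(sum(r for s, r in zip(signs, ranks) if s) - mu)
        if dist > observed + 1e-9:
            beyond += 1
        elif dist >= observed - 1e-9:
            ties += 1
    if convention == "inclusive":
        return (beyond + ties) / 2**n
    return (beyond + 0.5 * ties) / 2**n


class TestValidDay:
    def test_low_coverage_invalid(self):
        assert sa.valid_day(make_day(coverage=0.29), make_log()) is False

    def test_coverage_at_threshold_valid(self):
        assert sa.valid_day(make_day(coverage=0.30), make_log()) is True

    def test_zero_distance_with_pushes_is_abnormal(self):
        day = make_day(coverage=0.6, push_total=500, distance_m=0.0, rotations_total=0.0)
        assert sa.valid_day(day, make_log()) is False

    def test_silent_wheel_on_active_day_is_abnormal(self):
        day = make_day(push_total=0, distance_m=0.0, rotations_total=0.0, nonsed=100)
        assert sa.valid_day(day, make_log()) is False

    def test_consistent_day_valid(self):
        assert sa.valid_day(make_day(), make_log()) is True

    def test_atypical_day_invalid(self):
        assert sa.valid_day(make_day(), make_log(typical=False)) is False

    def test_missing_log_entry_excludes(self):
        assert sa.valid_day(make_day(), None) is False


class TestPhaseMeans:
    def test_single_day_equals_that_day(self):
        summary = sa.phase_means([make_day(mvpa=33)], "01", "baseline")
        assert summary.exercise_time_min == 33.0
        assert summary.n_valid_days == 1

    def test_mean_of_20_and_40_is_30(self):
        days = [make_day(mvpa=20), make_day(mvpa=40)]
        summary = sa.phase_means(days, "01", "intervention")
        assert summary.exercise_time_min == pytest.approx(30.0)

    def test_zero_valid_days_flagged(self):
        with pytest.raises(ValueError, match="no valid"):
            sa.phase_means([], "01", "baseline")


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,intervention,expected",
        [
            (26.8, 99.0, 269),
            (1.1, 9.9, 800),
            (5.0, 5.0, 0),
            (200.0, 201.0, 1),  # 0.5 % rounds half away from zero
            (200.0, 199.0, -1),
            (0.8, 0.7, -13),
        ],
    )
    def test_examples(self, baseline, intervention, expected):
        assert sa.percent_change(baseline, intervention) == expected

    def test_zero_baseline_undefined(self):
        assert sa.percent_change(0.0, 10.0) is None

    @given(
        b=st.floats(0.5, 100.0),
        k=st.floats(-0.9, 9.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, b, k):
        raw = 100.0 * k
        expected = int(math.copysign(math.floor(abs(raw) + 0.5), raw))
        assert sa.percent_change(b, b * (1.0 + k)) == pytest.approx(expected, abs=1)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "pct,category",
        [
            (16, sa.CONSIDERABLE_INCREASE),
            (8, sa.NO_CONSIDERABLE_CHANGE),
            (-64, sa.CONSIDERABLE_DECREASE),
            (10, sa.NO_CONSIDERABLE_CHANGE),  # boundary is not considerable
            (-10, sa.NO_CONSIDERABLE_CHANGE),
            (11, sa.CONSIDERABLE_INCREASE),
            (-11, sa.CONSIDERABLE_DECREASE),
            (None, None),
        ],
    )
    def test_rule(self, pct, category):
        assert sa.classify_change(pct) == category


class TestWilcoxon:
    def test_normal_p_close_to_exact_enumeration_n6(self, rng):
        for _ in range(20):
            baseline = rng.normal(10, 3, size=6)
            intervention = baseline + rng.normal(0.5, 3, size=6)
            result = sa.wilcoxon_signed_rank(baseline, intervention)
            exact = exact_wilcoxon_p_two_sided(baseline, intervention)
            assert abs(result.p_two_sided - exact) < 0.05

    def test_rank_conservation(self, rng):
        baseline = rng.normal(size=12)
        intervention = baseline + rng.normal(size=12)
        result = sa.wilcoxon_signed_rank(baseline, intervention)
        n = result.n
        assert result.w_plus + result.w_minus == pytest.approx(n * (n + 1) / 2)

    def test_antisymmetry_under_pair_swap(self, rng):
        baseline = rng.normal(size=10)
        intervention = baseline + rng.normal(size=10)
        forward = sa.wilcoxon_signed_rank(baseline, intervention)
        backward = sa.wilcoxon_signed_rank(intervention, baseline)
        assert forward.statistic == pytest.approx(-backward.statistic)
        assert abs(forward.statistic) == pytest.approx(abs(backward.statistic))

    def test_ties_use_average_ranks(self):
        baseline = np.zeros(6)
        intervention = np.array([1.0, 1.0, 1.0, 1.0, -1.0, 2.0])
        result = sa.wilcoxon_signed_rank(baseline, intervention)
        # |d| = 1 five times -> ranks 3 each; |d| = 2 -> rank 6
        assert result.w_plus == pytest.approx(4 * 3 + 6)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            sa.wilcoxon_signed_rank(np.ones(8), np.ones(8))

    def test_too_few_nonzero_differences(self):
        baseline = np.ones(6)
        intervention = np.array([1, 1, 1, 1, 2, 3], dtype=float)
        with pytest.raises(ValueError, match="at least 5"):
            sa.wilcoxon_signed_rank(baseline, intervention)


class TestPairedT:
    def test_matches_closed_form(self, rng):
        baseline = rng.normal(30, 5, size=16)
        intervention = baseline + rng.normal(2, 4, size=16)
        result = sa.paired_t(baseline, intervention)
        d = intervention - baseline
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(16))
        assert result.statistic == pytest.approx(expected_t, abs=1e-12)
        assert result.df == 15
        assert result.cohens_dz == pytest.approx(d.mean() / d.std(ddof=1))

    def test_cross_checks_scipy(self, rng):
        baseline = rng.normal(size=10)
        intervention = baseline + rng.normal(size=10)
        result = sa.paired_t(baseline, intervention)
        ref = stats.ttest_rel(intervention, baseline)
        assert result.statistic == pytest.approx(ref.statistic)
        assert result.p_two_sided == pytest.approx(ref.pvalue)

    def test_one_sided_p_is_half_two_sided_for_positive_t(self, rng):
        baseline = np.arange(10.0)
        intervention = baseline + np.linspace(1, 2, 10)
        result = sa.paired_t(baseline, intervention)
        assert result.p_one_sided == pytest.approx(result.p_two_sided / 2)

    def test_identical_pairs_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sa.paired_t(np.ones(8), np.ones(8) + 2.0)


class TestPowerSampleSize:
    def test_huge_effect_gives_minimum_n(self):
        assert sa.power_sample_size(effect_d=50.0) == 2

    def test_definition_bracketing(self):
        n = sa.power_sample_size(0.5, power=0.8, alpha=0.05, sided=2)
        assert sa._paired_t_power(n, 0.5, 0.05, 2) >= 0.8
        assert sa._paired_t_power(n - 1, 0.5, 0.05, 2) < 0.8

    def test_matches_monte_carlo_oracle(self):
        n_analytic = sa.power_sample_size(0.5, power=0.8, alpha=0.05, sided=2)
        rng = np.random.default_rng(0)

        def mc_power(n, reps=4000):
            diffs = rng.normal(0.5, 1.0, size=(reps, n))
            t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
            crit = stats.t.isf(0.025, n - 1)
            return np.mean(np.abs(t) > crit)

        # smallest adequate n by simulation, within +-1 of the analytic answer
        candidates = range(max(n_analytic - 2, 2), n_analytic + 3)
        powers = {n: mc_power(n) for n in candidates}
        mc_n = min((n for n, p in powers.items() if p >= 0.8), default=None)
        assert mc_n is not None and abs(mc_n - n_analytic) <= 1

    @pytest.mark.parametrize("kwargs", [
        {"effect_d": -1.0},
        {"effect_d": 0.5, "power": 1.0},
        {"effect_d": 0.5, "alpha": 0.0},
        {"effect_d": 0.5, "sided": 3},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            sa.power_sample_size(**kwargs)


@pytest.fixture(scope="module")
def result():
    return sa.summarize_study(sa.load_cohort_fixture())


class TestSummarizeStudy:
    def test_change_counts_partition_participants(self, result):
        assert sum(result.change_counts.values()) == 16

    def test_report_frame_has_mean_sd_row(self, result):
        frame = sa.report_frame(result)
        assert len(frame) == 17
        last = frame.iloc[-1]
        assert last["participant_id"] == "Mean (SD)"
        assert last["exercise_time_baseline"] == "26.4 (16.9)"

    def test_tests_present_for_expected_variables(self, result):
        assert set(result.tests) == {"exercise_time", "sedentary_breaks", "eses"}
        assert result.tests["eses"].test == "paired_t"

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            sa.summarize_study(sa.load_cohort_fixture().head(4))

    def test_pipeline_cohort_round_trip(self):
        from wheelpa.synthetic_data import generate_table2_like_cohort
        import pandas as pd

        cohort = generate_table2_like_cohort(12, effect=8.0, seed=21)
        frame = pd.DataFrame(
            {
                "participant_id": [b.participant_id for b, _ in cohort],
                "exercise_time_baseline": [b.exercise_time_min for b, _ in cohort],
                "exercise_time_intervention": [i.exercise_time_min for _, i in cohort],
            }
        )
        result = sa.summarize_study(frame)
        assert sum(result.change_counts.values()) == 12
        assert "exercise_time" in result.tests
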