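import math

import numpy as np
import pytest
from scipy import stats

from dogsleep.comparison import (
    AD_CRITICAL_5PCT,
    PairedSessions,
    SessionPair,
    ZeroVarianceError,
    anderson_darling_normality,
    column_summary,
    comparison_report,
    frame_agreement,
    load_reference_sessions,
    one_sample_t_test,
    paired_t_test,
    percent_of_time,
    symmetric_percent_difference,
)
from dogsleep.sleep_state import SleepSummary

import oracles
from conftest import seq


def make_summary(sleep_s, awake_s, bouts=1, unknown_s=0.0, sid="x"):
    return SleepSummary(sid, sleep_s, awake_s, unknown_s,
                        sleep_s + awake_s + unknown_s, bouts,
                        100 * sleep_s / (sleep_s + awake_s) if sleep_s + awake_s else None)


class TestFrameAgreement:
    def test_identical_sequences_100(self):
        s = seq("SWSWSW")
        assert frame_agreement(s, s) == 100.0

    def test_complementary_sequences_0(self):
        assert frame_agreement(seq("SWSW"), seq("WSWS")) == 0.0

    def test_5340_matches_of_6000_is_89_percent(self):
        a = seq("S" * 6000)
        b = seq("S" * 5340 + "W" * 660)
        assert frame_agreement(a, b) == pytest.approx(89.0)

    def test_unknown_frames_excluded_from_comparison(self):
        a = seq("SSUW")
        b = seq("SWSW")
        # jointly known: frames 0, 1, 3 -> matches at 0 and 3
        assert frame_agreement(a, b) == pytest.approx(100 * 2 / 3)

    def test_symmetric(self, rng):
        pat_a = "".join(rng.choice(list("SWU"), size=100))
        pat_b = "".join(rng.choice(list("SWU"), size=100))
        a, b = seq(pat_a), seq(pat_b)
        assert frame_agreement(a, b) == frame_agreement(b, a)

    def test_no_jointly_known_frames_raises(self):
        with pytest.raises(ValueError, match="jointly known"):
            frame_agreement(seq("UUS"), seq("SSU"))


class TestPairedT:
    def test_hand_computed_example(self):
        # d = [1,2,3], mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = paired_t_test([1, 2, 3], [0, 0, 0])
        assert res.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(oracles.oracle_t_sf_by_integration(
            res.statistic, 2) * 2, rel=1e-9)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.0])

    def test_antisymmetric_in_arguments(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = paired_t_test(x, y)
        b = paired_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p == b.p

    def test_matches_brute_force_oracle_to_1e9(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.normal(10, 3, n)
            y = x + rng.normal(0.5, 2, n)
            res = paired_t_test(x, y)
            t, df, p = oracles.oracle_paired_t(x, y)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.df == df
            assert res.p == pytest.approx(p, abs=1e-9)
            assert res.p == pytest.approx(
                2 * oracles.oracle_t_sf_by_integration(t, df), abs=1e-9)

    def test_agrees_with_scipy_reference(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        res = paired_t_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestAndersonDarling:
    def test_evenly_spaced_small_sample_not_rejected(self):
        res = anderson_darling_normality(list(range(1, 12)))
        assert res.statistic < AD_CRITICAL_5PCT
        assert not res.significant

    def test_constant_sample_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            anderson_darling_normality([5.0] * 10)

    def test_requires_five_observations(self):
        with pytest.raises(ValueError):
            anderson_darling_normality([1.0, 2.0, 3.0, 4.0])

    def test_heavy_tailed_sample_rejected(self):
        rng = np.random.default_rng(7)
        x = list(rng.normal(0, 1, 50)) + [25.0]
        res = anderson_darling_normality(x)
        assert res.significant

    @pytest.mark.filterwarnings("ignore::FutureWarning")
    def test_statistic_matches_scipy_reference(self, rng):
        for _ in range(10):
            x = rng.normal(5, 2, int(rng.integers(8, 40)))
            ours = anderson_darling_normality(x)
            ref = stats.anderson(x, dist="norm")
            n = len(x)
            ref_corrected = ref.statistic * (1 + 0.75 / n + 2.25 / n ** 2)
            assert ours.statistic == pytest.approx(ref_corrected, rel=1e-9)

    def test_rejection_rate_calibrated_at_5pct(self):
        """Under H0 (normal data, n = 30), rejects at 0.05 +/- 0.02."""
        rng = np.random.default_rng(2024)
        rejections = sum(
            anderson_darling_normality(rng.normal(0, 1, 30)).significant
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestSummaries:
    def test_percent_of_time(self):
        assert percent_of_time(make_summary(6 * 3600, 6 * 3600)) == 50.0
        assert percent_of_time(make_summary(0, 100)) == 0.0
        assert percent_of_time(make_summary(43556, 21244)) == pytest.approx(67.22, abs=0.005)

    def test_percent_of_time_requires_known_time(self):
        with pytest.raises(ValueError):
            percent_of_time(make_summary(0, 0, unknown_s=10))

    def test_column_summary_textbook_case(self):
        mean, sd, lo, hi = column_summary([1, 2, 3])
        assert (mean, sd, lo, hi) == (2.0, 1.0, 1.0, 3.0)

    def test_column_summary_single_value_has_no_sd(self):
        mean, sd, lo, hi = column_summary([7.0])
        assert mean == 7.0 and sd is None

    def test_column_summary_rejects_empty(self):
        with pytest.raises(ValueError):
            column_summary([])

    def test_symmetric_percent_difference(self):
        assert symmetric_percent_difference(100, 100) == 0.0
        assert symmetric_percent_difference(110, 90) == pytest.approx(20.0)
        assert symmetric_percent_difference(90, 110) == pytest.approx(20.0)


class TestReferenceDataset:
    def test_duration_test_reproduces_published_statistic(self):
        paired = load_reference_sessions()
        res = comparison_report(paired).tests["sleep_duration_t"]
        assert res.statistic == pytest.approx(2.805, abs=0.001)
        assert res.df == 10
        assert res.p == pytest.approx(0.019, abs=0.001)
        assert res.significant

    def test_bout_columns_match_published_summaries(self):
        paired = load_reference_sessions()
        report = comparison_report(paired)
        bs = report.column_summaries["bouts_system"]
        bm = report.column_summaries["bouts_manual"]
        assert bs["mean"] == pytest.approx(15.0)
        assert bs["sd"] == pytest.approx(5.0, abs=0.05)
        assert bm["mean"] == pytest.approx(16.0, abs=0.5)
        assert bm["sd"] == pytest.approx(3.5, abs=0.05)

    def test_percent_difference_column_summaries(self):
        report = comparison_report(load_reference_sessions())
        pd = report.column_summaries["pct_diff_sleep"]
        assert pd["mean"] == pytest.approx(0.88, abs=0.005)
        assert pd["max"] == pytest.approx(2.68)

    def test_percent_of_time_and_bout_tests_not_significant(self):
        report = comparison_report(load_reference_sessions())
        assert not report.tests["bout_count_t"].significant
        assert not report.tests["percent_of_time_t"].significant

    def test_rows_render_durations_as_hms(self):
        report = comparison_report(load_reference_sessions())
        assert report.rows[0]["sleep_system"] == "12:05:56"
        assert report.rows[0]["sleep_manual"] == "09:31:33"
        assert len(report.rows) == 11


class TestComparisonReport:
    def test_identical_sessions_reported_as_degenerate(self):
        pairs = [SessionPair(i, make_summary(100 + i, 50), make_summary(100 + i, 50))
                 for i in range(3)]
        report = comparison_report(PairedSessions(pairs))
        assert report.tests["sleep_duration_t"] == "identical"

    def test_two_session_report_cross_checked_by_hand(self):
        pairs = [
            SessionPair(1, make_summary(1000, 500, bouts=3), make_summary(900, 600, bouts=4)),
            SessionPair(2, make_summary(800, 700, bouts=5), make_summary(500, 1000, bouts=2)),
        ]
        report = comparison_report(PairedSessions(pairs))
        # differences: [100, 300] -> mean 200, sd 141.42..., t = 2
        res = report.tests["sleep_duration_t"]
        assert res.statistic == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1
        # percent-of-time from the summaries' own percent columns
        pct = report.tests["percent_of_time_t"]
        t, df, p = oracles.oracle_paired_t(
            [100 * 1000 / 1500, 100 * 800 / 1500],
            [100 * 900 / 1500, 100 * 500 / 1500])
        assert pct.statistic == pytest.approx(t, abs=1e-9)

    def test_one_sample_test_equals_paired_against_constant(self, rng):
        x = rng.normal(1, 2, 10)
        a = one_sample_t_test(x, 0.0)
        b = paired_t_test(x, np.zeros(10))
        assert a.statistic == b.statistic and a.p == b.p
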