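"""Daily unique-user series, gap interpolation and volume statistics."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lonelytext.volume_timeseries import (daily_unique_users,
                                          interpolate_gaps, posts_per_account,
                                          series_correlation, window_compare)
from tests.conftest import series_from_values


class TestDailyUniqueUsers:
    def test_repeat_posts_count_once_per_day(self, make_tweet):
        from datetime import datetime, timezone
        when = datetime(2020, 3, 1, tzinfo=timezone.utc)
        tweets = [make_tweet(tweet_id=i, user_id=7, when=when, gender="female")
                  for i in range(3)]
        series = daily_unique_users(tweets, "female")
        assert series.value_on(date(2020, 3, 1)) == 1

    def test_two_users_same_day(self, make_tweet):
        tweets = [make_tweet(tweet_id=1, user_id=1, gender="female"),
                  make_tweet(tweet_id=2, user_id=2, gender="female")]
        series = daily_unique_users(tweets, "female")
        assert series.value_on(date(2020, 3, 1)) == 2

    def test_day_without_tweets_is_zero(self, make_tweet):
        tweets = [make_tweet(gender="female")]
        series = daily_unique_users(tweets, "female",
                                    start=date(2020, 2, 28),
                                    end=date(2020, 3, 2))
        assert series.value_on(date(2020, 2, 29)) == 0

    def test_invariant_to_duplicated_tweets(self, small_setup):
        _, tweets, _, truth = small_setup
        sample = [t.with_gender(truth.user_gender[t.user.id])
                  for t in tweets[:500]]
        a = daily_unique_users(sample, "female")
        b = daily_unique_users(sample + sample, "female")
        assert (a.counts == b.counts).all()


class TestInterpolateGaps:
    def test_midpoint(self):
        s = series_from_values([100, 120, 200])
        out = interpolate_gaps(s, [date(2020, 3, 2)])
        assert out.value_on(date(2020, 3, 2)) == pytest.approx(150.0)
        assert out.value_on(date(2020, 3, 1)) == 100.0

    def test_three_day_gap_quarter_points(self):
        s = series_from_values([100, 1, 2, 3, 400])
        outages = [date(2020, 3, 2), date(2020, 3, 3), date(2020, 3, 4)]
        out = interpolate_gaps(s, outages)
        assert [out.value_on(d) for d in outages] == [175.0, 250.0, 325.0]
        assert out.interpolated == frozenset(outages)

    def test_empty_outage_set_is_identity(self):
        s = series_from_values([5, 6, 7])
        out = interpolate_gaps(s, [])
        assert (out.counts == s.counts).all()

    def test_boundary_outage_has_no_flank(self):
        s = series_from_values([1, 2, 3])
        with pytest.raises(ValueError, match="boundary"):
            interpolate_gaps(s, [date(2020, 3, 1)])

    def test_outside_index_rejected(self):
        s = series_from_values([1, 2, 3])
        with pytest.raises(ValueError, match="outside"):
            interpolate_gaps(s, [date(2021, 1, 1)])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_exact_on_linear_series(self, seed):
        """Reconstruction error is zero on any globally linear series for
        an arbitrary interior outage set."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        intercept = rng.uniform(50, 100)
        slope = rng.uniform(-intercept / n, 5)  # keeps the line nonnegative
        values = intercept + slope * np.arange(n)
        s = series_from_values(values)
        interior = [date(2020, 3, 1) + timedelta(days=i)
                    for i in range(1, n - 1)]
        k = int(rng.integers(0, len(interior) + 1))
        outages = [interior[i]
                   for i in sorted(rng.choice(len(interior), size=k,
                                              replace=False))]
        out = interpolate_gaps(s, outages)
        assert np.allclose(out.counts.values, values, atol=1e-9)


class TestWindowCompare:
    def test_no_effect_constant_windows(self):
        s = series_from_values([100] * 14)
        wc = window_compare(s, date(2020, 3, 8))
        assert wc.mean_post - wc.mean_pre == 0
        assert wc.p_one_sided == pytest.approx(0.5)

    def test_clear_step_matches_hand_welch(self):
        pre = [100, 104, 98, 101, 99, 103, 100]
        post = [180, 185, 178, 190, 176, 184, 181]
        s = series_from_values(pre + post)
        wc = window_compare(s, date(2020, 3, 8))
        # independent Welch computation from the textbook formula
        m1, m2 = np.mean(post), np.mean(pre)
        v1, v2 = np.var(post, ddof=1) / 7, np.var(pre, ddof=1) / 7
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / 6 + v2 ** 2 / 6)
        p = sps.t.sf(t, df)
        assert wc.t_statistic == pytest.approx(t)
        assert wc.p_one_sided == pytest.approx(p)
        assert wc.p_one_sided < 0.05

    def test_window_exceeding_series_raises(self):
        s = series_from_values([1] * 10)
        with pytest.raises(ValueError):
            window_compare(s, date(2020, 3, 3))

    def test_split_day_belongs_to_post_window(self):
        values = [0] * 7 + [50] + [0] * 6
        s = series_from_values(values)
        wc = window_compare(s, date(2020, 3, 8))
        assert wc.mean_post == pytest.approx(50 / 7)
        assert wc.mean_pre == 0.0


class TestSeriesCorrelation:
    def test_identical_series(self):
        s = series_from_values([1, 5, 3, 8])
        assert series_correlation(s, s) == pytest.approx(1.0)

    def test_mirrored_series(self):
        values = np.array([1.0, 5, 3, 8])
        mirrored = 2 * values.mean() - values
        assert series_correlation(
            series_from_values(values),
            series_from_values(mirrored)) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined_not_a_crash(self):
        assert np.isnan(series_correlation(series_from_values([2, 2, 2]),
                                           series_from_values([1, 2, 3])))

    def test_independent_series_have_near_zero_correlation(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(100):
            a = series_from_values(rng.poisson(100, size=730))
            b = series_from_values(rng.poisson(100, size=730))
            if abs(series_correlation(a, b)) >= 0.15:
                rejections += 1
        assert rejections <= 5  # |r| < 0.15 in at least 95% of replicates


class TestPostsPerAccount:
    def test_all_single_posters(self, make_tweet):
        tweets = [make_tweet(tweet_id=i, user_id=i,
                             gender="female" if i % 2 else "male")
                  for i in range(1, 9)]
        res = posts_per_account(tweets)
        assert res.mean_female == 1.0 and res.mean_male == 1.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_fully_separated_counts_give_u_zero(self, make_tweet):
        tweets = []
        tid = 1
        for uid in (1, 2, 3):  # female users: 1 post each
            tweets.append(make_tweet(tweet_id=tid, user_id=uid,
                                     gender="female"))
            tid += 1
        for uid in (11, 12, 13):  # male users: 5 posts each
            for _ in range(5):
                tweets.append(make_tweet(tweet_id=tid, user_id=uid,
                                         gender="male"))
                tid += 1
        res = posts_per_account(tweets)
        assert res.u_statistic == 0.0
        assert res.p_two_sided < 0.2

    def test_missing_gender_group_is_undefined(self, make_tweet):
        res = posts_per_account([make_tweet(gender="female")])
        assert np.isnan(res.p_two_sided)
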