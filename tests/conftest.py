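"""Shared fixtures: generated corpora at two scales and a tweet factory."""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pandas as pd
import pytest

from lonelytext.corpus import TweetRecord, UserSnapshot
from lonelytext.synthetic_corpus import GeneratorConfig, generate_corpus
from lonelytext.volume_timeseries import DailyVolumeSeries


@pytest.fixture(scope="session")
def small_setup():
    """Two-month corpus straddling the lockdown date, all contaminant and
    spam machinery active, at a scale where the whole pipeline runs in
    well under a second."""
    config = GeneratorConfig(
        n_users_per_gender=300, base_daily_rate=20.0, lockdown_multiplier=1.8,
        study_start="2020-02-15", lockdown_date="2020-03-15",
        study_end="2020-04-15", spam_fraction=0.10, seed=1234)
    tweets, users, truth = generate_corpus(config)
    return config, tweets, users, truth


@pytest.fixture(scope="session")
def marker_setup():
    """Marker-recovery scale: ~20k disclosure posts per gender with the
    planted 5x lexical effect."""
    config = GeneratorConfig(
        n_users_per_gender=2000, base_daily_rate=200.0,
        lockdown_multiplier=1.0, spam_fraction=0.02,
        study_start="2020-01-01", lockdown_date="2020-02-15",
        study_end="2020-04-09", seed=20200315)
    tweets, users, truth = generate_corpus(config)
    return config, tweets, users, truth


@pytest.fixture
def make_tweet():
    """Factory for hand-built tweets with sensible defaults."""
    def factory(tweet_id=1, text="i feel lonely tonight", lang="en",
                when=datetime(2020, 3, 1, 12, 0, tzinfo=timezone.utc),
                user_id=1, name="Alice B.",
                created=datetime(2015, 1, 1, tzinfo=timezone.utc),
                statuses=500, retweeted=False, urls=(), reply=0, retweet=0,
                like=0, quote=0, gender=None):
        return TweetRecord(
            id=tweet_id, created_at=when, text=text, lang=lang,
            user=UserSnapshot(id=user_id, name=name, created_at=created,
                              statuses_count=statuses),
            retweeted=retweeted, urls=tuple(urls), reply_count=reply,
            retweet_count=retweet, like_count=like, quote_count=quote,
            gender=gender)
    return factory


def series_from_values(values, start=date(2020, 3, 1), gender="female"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailyVolumeSeries(counts=pd.Series([float(v) for v in values],
                                              index=idx), gender=gender)


@pytest.fixture
def make_series():
    return series_from_values
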