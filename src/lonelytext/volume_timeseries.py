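"""Daily unique-user posting volume: gap repair and lockdown comparisons.

Volume is measured in unique authors per UTC calendar day (counting users
rather than posts prevents prolific accounts from dominating).  Collection
outage days are repaired by linear interpolation between the flanking
observed days.  The lockdown step is assessed with a one-sided Welch
two-sample t-test on the windows around the split date, co-movement of the
two gender series with the Pearson correlation, and per-account posting
intensity with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus import TweetRecord
from .engagement_stats import mann_whitney

FEMALE = "female"
MALE = "male"


@dataclass
class DailyVolumeSeries:
    """Contiguous date-indexed unique-user counts, with the set of dates
    whose values were filled by interpolation."""

    counts: pd.Series  # index: contiguous daily DatetimeIndex
    gender: str | None = None
    interpolated: frozenset = frozenset()

    def __post_init__(self):
        idx = self.counts.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise ValueError("series index must be contiguous daily dates")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    def value_on(self, day: date) -> float:
        return float(self.counts.loc[pd.Timestamp(day)])

    @property
    def dates(self) -> list[date]:
        return [ts.date() for ts in self.counts.index]


def daily_unique_users(tweets: Iterable[TweetRecord], gender: str,
                       start: date | None = None,
                       end: date | None = None) -> DailyVolumeSeries:
    """Unique authors per UTC day among the given gender's posts; each user
    contributes at most one to each day regardless of post count."""
    seen: dict[date, set[int]] = {}
    days_present = []
    for t in tweets:
        if t.gender != gender:
            continue
        d = t.day
        days_present.append(d)
        seen.setdefault(d, set()).add(t.user.id)
    if start is None:
        start = min(days_present) if days_present else date(2019, 3, 15)
    if end is None:
        end = max(days_present) if days_present else start
    idx = pd.date_range(start, end, freq="D")
    counts = pd.Series(
        [len(seen.get(ts.date(), ())) for ts in idx], index=idx, dtype=float)
    return DailyVolumeSeries(counts=counts, gender=gender)


def interpolate_gaps(series: DailyVolumeSeries,
                     outage_dates: Iterable[date]) -> DailyVolumeSeries:
    """Replace each maximal run of outage days with the linear segment
    between the flanking observed values; all other values are unchanged.
    Interpolated values are left as reals, since they feed means rather
    than counts."""
    outages = {d if isinstance(d, date) else pd.Timestamp(d).date()
               for d in outage_dates}
    if not outages:
        return DailyVolumeSeries(series.counts.copy(), series.gender,
                                 series.interpolated)
    index_dates = set(series.dates)
    missing = outages - index_dates
    if missing:
        raise ValueError(f"outage dates outside series index: {sorted(missing)}")
    first, last = series.dates[0], series.dates[-1]
    for d in outages:
        run_start = d
        while run_start - timedelta(days=1) in outages:
            run_start -= timedelta(days=1)
        run_end = d
        while run_end + timedelta(days=1) in outages:
            run_end += timedelta(days=1)
        if run_start == first or run_end == last:
            raise ValueError(
                f"outage run {run_start}..{run_end} touches the series "
                "boundary; no flanking observed day to interpolate from")
    values = series.counts.copy()
    mask = pd.Series([ts.date() in outages for ts in values.index],
                     index=values.index)
    values[mask] = np.nan
    values = values.interpolate(method="linear")
    return DailyVolumeSeries(
        counts=values, gender=series.gender,
        interpolated=frozenset(series.interpolated) | frozenset(outages))


@dataclass(frozen=True)
class WindowComparison:
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    t_statistic: float
    p_one_sided: float
    window_days: int
    split_date: date


def window_compare(series: DailyVolumeSeries, split_date: date,
                   window_days: int = 7) -> WindowComparison:
    """Welch one-sided t-test (post > pre) on the ``window_days`` days
    strictly before the split date vs. the ``window_days`` days from the
    split date on (the split day itself counts as post)."""
    split = pd.Timestamp(split_date)
    pre = series.counts.loc[split - pd.Timedelta(days=window_days):
                            split - pd.Timedelta(days=1)]
    post = series.counts.loc[split:split + pd.Timedelta(days=window_days - 1)]
    if len(pre) != window_days or len(post) != window_days:
        raise ValueError("comparison windows exceed the series extent")
    pre_v, post_v = pre.values, post.values
    if pre_v.std(ddof=1) == 0 and post_v.std(ddof=1) == 0:
        # degenerate: no within-window variation; direction of the means
        # is all the data can say
        if post_v.mean() > pre_v.mean():
            t_stat, p = float("inf"), 0.0
        elif post_v.mean() < pre_v.mean():
            t_stat, p = float("-inf"), 1.0
        else:
            t_stat, p = 0.0, 0.5
    else:
        t_stat, p = sps.ttest_ind(post_v, pre_v, equal_var=False,
                                  alternative="greater")
    return WindowComparison(
        mean_pre=float(pre_v.mean()), sd_pre=float(pre_v.std(ddof=1)),
        mean_post=float(post_v.mean()), sd_post=float(post_v.std(ddof=1)),
        t_statistic=float(t_stat), p_one_sided=float(p),
        window_days=window_days, split_date=split_date)


def series_correlation(series_f: DailyVolumeSeries,
                       series_m: DailyVolumeSeries) -> float:
    """Pearson product-moment correlation of the two daily series;
    ``nan`` when either series has zero variance."""
    x = series_f.counts.values
    y = series_m.counts.values
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PostsPerAccount:
    mean_female: float
    sd_female: float
    mean_male: float
    sd_male: float
    n_female: int
    n_male: int
    u_statistic: float
    p_two_sided: float


def posts_per_account(tweets: Iterable[TweetRecord]) -> PostsPerAccount:
    """Per-user post counts by gender, with a tie-corrected two-sided
    Mann-Whitney U comparison; undefined (nan fields) when a gender has
    no users."""
    per_user: dict[int, int] = {}
    gender_of: dict[int, str] = {}
    for t in tweets:
        per_user[t.user.id] = per_user.get(t.user.id, 0) + 1
        gender_of[t.user.id] = t.gender
    f = np.array(sorted(c for u, c in per_user.items() if gender_of[u] == FEMALE),
                 dtype=float)
    m = np.array(sorted(c for u, c in per_user.items() if gender_of[u] == MALE),
                 dtype=float)
    if len(f) == 0 or len(m) == 0:
        nan = float("nan")
        return PostsPerAccount(
            mean_female=f.mean() if len(f) else nan,
            sd_female=f.std(ddof=1) if len(f) > 1 else nan,
            mean_male=m.mean() if len(m) else nan,
            sd_male=m.std(ddof=1) if len(m) > 1 else nan,
            n_female=len(f), n_male=len(m), u_statistic=nan, p_two_sided=nan)
    u, p = mann_whitney(f, m)
    return PostsPerAccount(
        mean_female=float(f.mean()),
        sd_female=float(f.std(ddof=1)) if len(f) > 1 else 0.0,
        mean_male=float(m.mean()),
        sd_male=float(m.std(ddof=1)) if len(m) > 1 else 0.0,
        n_female=len(f), n_male=len(m),
        u_statistic=float(u), p_two_sided=float(p))


def series_to_frame(series_f: DailyVolumeSeries,
                    series_m: DailyVolumeSeries) -> pd.DataFrame:
    """CSV-ready frame: date, female_count, male_count, interpolated."""
    if list(series_f.counts.index) != list(series_m.counts.index):
        raise ValueError("gender series must share an index")
    interp = frozenset(series_f.interpolated) | frozenset(series_m.interpolated)
    return pd.DataFrame({
        "date": [ts.date().isoformat() for ts in series_f.counts.index],
        "female_count": series_f.counts.values,
        "male_count": series_m.counts.values,
        "interpolated": [int(ts.date() in interp) for ts in series_f.counts.index],
    })
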