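"""Engagement comparison: likes, retweets, replies and quotes by gender.

Response counts on social posts are long-tailed and zero-heavy (medians of
0, or 1 for likes, are the norm), so distributions are compared with the
non-parametric Mann-Whitney U test with tie correction, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .corpus import TweetRecord

FEMALE = "female"
MALE = "male"
METRICS = ("like_count", "retweet_count", "reply_count", "quote_count")


class EngagementDataError(ValueError):
    pass


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float],
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-sum U (for the first sample) and p-value.

    Exact enumeration when both samples are small (n <= 20) and tie-free;
    tie-corrected normal approximation otherwise.  Fully tied data carry no
    ordering information: U = n1*n2/2, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EngagementDataError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MetricSummary:
    n: int
    mean: float
    median: float
    maximum: float


@dataclass
class EngagementSummary:
    """Per gender and per metric: n/mean/median/max, pairwise Mann-Whitney
    p per metric, and the share of posts with zero response overall."""

    per_gender: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    zero_response: dict = field(default_factory=dict)

    def to_report(self) -> dict:
        report = {}
        for metric in METRICS:
            report[metric] = {}
            for gender in (FEMALE, MALE):
                ms = self.per_gender.get(gender, {}).get(metric)
                if ms is not None:
                    report[metric][gender] = {
                        "n": ms.n, "mean": ms.mean,
                        "median": ms.median, "max": ms.maximum}
            if metric in self.p_values:
                report[metric]["mann_whitney_p"] = self.p_values[metric]
        report["zero_response_fraction"] = dict(self.zero_response)
        return report


def _metric_values(tweets: Sequence[TweetRecord], metric: str) -> np.ndarray:
    values = []
    for t in tweets:
        v = getattr(t, metric, None)
        if v is None or v < 0:
            raise EngagementDataError(
                f"tweet {t.id}: missing or negative {metric}")
        values.append(v)
    return np.asarray(values, dtype=float)


def engagement_summary(tweets: Sequence[TweetRecord]) -> EngagementSummary:
    summary = EngagementSummary()
    groups = {g: [t for t in tweets if t.gender == g] for g in (FEMALE, MALE)}
    for gender, group in groups.items():
        summary.per_gender[gender] = {}
        for metric in METRICS:
            if not group:
                continue
            v = _metric_values(group, metric)
            summary.per_gender[gender][metric] = MetricSummary(
                n=v.size, mean=float(v.mean()), median=float(np.median(v)),
                maximum=float(v.max()))
        if group:
            allzero = [all(getattr(t, m) == 0 for m in METRICS) for t in group]
            summary.zero_response[gender] = float(np.mean(allzero))
    for metric in METRICS:
        f, m = groups[FEMALE], groups[MALE]
        if f and m:
            _, p = mann_whitney(_metric_values(f, metric),
                                _metric_values(m, metric))
            summary.p_values[metric] = p
    return summary


def compare_distributions(values_f: Sequence[float],
                          values_m: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and two-sided p."""
    return mann_whitney(values_f, values_m, alternative="two-sided")


def zero_reply_fraction(tweets: Sequence[TweetRecord]) -> float:
    """Share of posts with zero replies; nan on empty input."""
    if not tweets:
        return float("nan")
    values = _metric_values(tweets, "reply_count")
    return float(np.mean(values == 0))


def stratified_subsample(tweets: Sequence[TweetRecord], n_per_gender: int,
                         seed: int = 0) -> list[TweetRecord]:
    """Seeded subsample, uniform in time and across genders: within each
    gender, days are sampled round-robin so the draw is spread over the
    collection period (mirrors a re-collection sampled uniformly in time)."""
    rng = np.random.default_rng(seed)
    out: list[TweetRecord] = []
    for gender in (FEMALE, MALE):
        by_day: dict = {}
        for t in tweets:
            if t.gender == gender:
                by_day.setdefault(t.day, []).append(t)
        days = sorted(by_day)
        pools = {d: list(rng.permutation(len(by_day[d]))) for d in days}
        picked: list[TweetRecord] = []
        while len(picked) < n_per_gender and any(pools[d] for d in days):
            for d in days:
                if pools[d] and len(picked) < n_per_gender:
                    picked.append(by_day[d][pools[d].pop()])
        out.extend(picked)
    return out
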