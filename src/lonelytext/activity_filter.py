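"""Posting-rate spam screen.

Each collected post embeds the author profile as of posting time, so a
user's activity is the time-ordered sequence of (timestamp, cumulative
status count) snapshots.  An account is flagged when its lifetime posting
rate — latest cumulative count divided by days since account creation —
reaches 16 posts/day (once per waking hour), or when its cumulative count
*decreases* within the dataset (posts deleted, hidden or removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

from .corpus import TweetRecord, UserSnapshot

RATE_THRESHOLD = 16.0


class ActivityDataError(ValueError):
    pass


@dataclass
class UserActivity:
    """Time-ordered (tweet timestamp, statuses_count) observations."""

    user_id: int
    created_at: datetime
    observations: list[tuple[datetime, int]]

    def __post_init__(self):
        self.observations = sorted(self.observations, key=lambda o: o[0])
        for ts, count in self.observations:
            if count < 0:
                raise ActivityDataError(
                    f"user {self.user_id}: negative statuses_count {count}")
            if ts < self.created_at:
                raise ActivityDataError(
                    f"user {self.user_id}: observation at {ts} predates "
                    f"account creation {self.created_at}")


def posting_rate(activity: UserActivity) -> float:
    """Latest statuses_count over whole days active, clamped to >= 1 day."""
    if not activity.observations:
        raise ActivityDataError(
            f"user {activity.user_id}: no observations")
    latest_ts, latest_count = activity.observations[-1]
    whole_days = int((latest_ts - activity.created_at).total_seconds() // 86400)
    return latest_count / max(1, whole_days)


def flag_spam(activity: UserActivity,
              rate_threshold: float = RATE_THRESHOLD) -> tuple[bool, str | None]:
    """Flag at rate >= threshold (closed boundary) or on any strict
    decrease in statuses_count between ordered observations."""
    if posting_rate(activity) >= rate_threshold:
        return True, "rate"
    counts = [c for _, c in activity.observations]
    if any(b < a for a, b in zip(counts, counts[1:])):
        return True, "decreasing"
    return False, None


def build_activities(tweets: Iterable[TweetRecord]) -> dict[int, UserActivity]:
    obs: dict[int, list[tuple[datetime, int]]] = {}
    created: dict[int, datetime] = {}
    for t in tweets:
        obs.setdefault(t.user.id, []).append(
            (t.created_at, t.user.statuses_count))
        created[t.user.id] = t.user.created_at
    return {uid: UserActivity(uid, created[uid], o) for uid, o in obs.items()}


def apply_activity_filter(tweets: Sequence[TweetRecord],
                          users: Sequence[UserSnapshot] | None = None,
                          rate_threshold: float = RATE_THRESHOLD
                          ) -> tuple[list[TweetRecord], dict]:
    """Drop all posts by flagged accounts.

    When a user collection is supplied, every post's author must appear in
    it; activity is still reconstructed from the per-post snapshots, which
    is what the collection actually observes.
    Returns (kept tweets, report) where the report lists flagged user ids
    and removal counts by reason.
    """
    if users is not None:
        known = {u.id for u in users}
        for t in tweets:
            if t.user.id not in known:
                raise ActivityDataError(
                    f"tweet {t.id}: author {t.user.id} missing from user collection")
    activities = build_activities(tweets)
    flagged: dict[int, str] = {}
    for uid in sorted(activities):
        is_spam, reason = flag_spam(activities[uid], rate_threshold)
        if is_spam:
            flagged[uid] = reason
    kept = [t for t in tweets if t.user.id not in flagged]
    removed_by_reason: dict[str, int] = {"rate": 0, "decreasing": 0}
    for t in tweets:
        if t.user.id in flagged:
            removed_by_reason[flagged[t.user.id]] += 1
    report = {
        "flagged_users": flagged,
        "n_users_flagged": len(flagged),
        "n_tweets_removed": len(tweets) - len(kept),
        "removed_by_reason": removed_by_reason,
    }
    return kept, report
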