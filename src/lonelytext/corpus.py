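"""Tweet/user record containers and JSON-Lines corpus I/O.

A corpus is a pair of JSON-Lines files: ``tweets.jsonl`` (one object per
post, with the author's profile snapshot embedded, since each collected
post carries the profile as it was at posting time) and ``users.jsonl``
(one object per account, the latest snapshot).  Timestamps are ISO 8601
UTC with a trailing ``Z``; day boundaries throughout the package are UTC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

ISO_FMT = "%Y-%m-%dT%H:%M:%SZ"

TWEETS_FILE = "tweets.jsonl"
USERS_FILE = "users.jsonl"


class CorpusParseError(ValueError):
    """Malformed corpus record; carries the file and 1-based line number."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def parse_timestamp(value: str) -> datetime:
    return datetime.strptime(value, ISO_FMT).replace(tzinfo=timezone.utc)


def format_timestamp(value: datetime) -> str:
    if value.tzinfo is not None:
        value = value.astimezone(timezone.utc)
    return value.strftime(ISO_FMT)


@dataclass(frozen=True)
class UserSnapshot:
    """Author profile as embedded in a post: free-form display name, the
    account creation date and the cumulative number of statuses posted."""

    id: int
    name: str
    created_at: datetime
    statuses_count: int

    def to_obj(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "created_at": format_timestamp(self.created_at),
            "statuses_count": self.statuses_count,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "UserSnapshot":
        return cls(
            id=int(obj["id"]),
            name=str(obj["name"]),
            created_at=parse_timestamp(obj["created_at"]),
            statuses_count=int(obj["statuses_count"]),
        )


@dataclass(frozen=True)
class TweetRecord:
    """One post with its engagement counts and contamination markers.

    ``gender`` is not a platform field: it is attached by the gender
    inference stage and serialized only once present.
    """

    id: int
    created_at: datetime
    text: str
    lang: str
    user: UserSnapshot
    retweeted: bool = False
    urls: tuple[str, ...] = ()
    reply_count: int = 0
    retweet_count: int = 0
    like_count: int = 0
    quote_count: int = 0
    gender: str | None = None

    def to_obj(self) -> dict:
        obj = {
            "id": self.id,
            "created_at": format_timestamp(self.created_at),
            "text": self.text,
            "lang": self.lang,
            "user": self.user.to_obj(),
            "retweeted": self.retweeted,
            "urls": list(self.urls),
            "reply_count": self.reply_count,
            "retweet_count": self.retweet_count,
            "like_count": self.like_count,
            "quote_count": self.quote_count,
        }
        if self.gender is not None:
            obj["gender"] = self.gender
        return obj

    @classmethod
    def from_obj(cls, obj: dict) -> "TweetRecord":
        return cls(
            id=int(obj["id"]),
            created_at=parse_timestamp(obj["created_at"]),
            text=str(obj["text"]),
            lang=str(obj["lang"]),
            user=UserSnapshot.from_obj(obj["user"]),
            retweeted=bool(obj["retweeted"]),
            urls=tuple(obj["urls"]),
            reply_count=int(obj["reply_count"]),
            retweet_count=int(obj["retweet_count"]),
            like_count=int(obj["like_count"]),
            quote_count=int(obj["quote_count"]),
            gender=obj.get("gender"),
        )

    def with_gender(self, gender: str) -> "TweetRecord":
        return TweetRecord(**{**self.__dict__, "gender": gender})

    @property
    def day(self):
        return self.created_at.astimezone(timezone.utc).date()


def _write_jsonl(records: Iterable[dict], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for obj in records:
            fh.write(json.dumps(obj, ensure_ascii=False, separators=(",", ":")))
            fh.write("\n")


def _read_jsonl(path: Path) -> list[tuple[int, dict]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append((line_no, json.loads(line)))
            except json.JSONDecodeError as exc:
                raise CorpusParseError(path, line_no, f"invalid JSON: {exc}") from exc
    return out


def write_tweets(tweets: Sequence[TweetRecord], path: str | Path) -> None:
    _write_jsonl((t.to_obj() for t in tweets), Path(path))


def read_tweets(path: str | Path) -> list[TweetRecord]:
    tweets = []
    for line_no, obj in _read_jsonl(Path(path)):
        try:
            tweets.append(TweetRecord.from_obj(obj))
        except (KeyError, ValueError, TypeError) as exc:
            raise CorpusParseError(path, line_no, f"bad tweet record: {exc!r}") from exc
    return tweets


def write_users(users: Sequence[UserSnapshot], path: str | Path) -> None:
    _write_jsonl((u.to_obj() for u in users), Path(path))


def read_users(path: str | Path) -> list[UserSnapshot]:
    users = []
    for line_no, obj in _read_jsonl(Path(path)):
        try:
            users.append(UserSnapshot.from_obj(obj))
        except (KeyError, ValueError, TypeError) as exc:
            raise CorpusParseError(path, line_no, f"bad user record: {exc!r}") from exc
    return users


def write_corpus(tweets: Sequence[TweetRecord], users: Sequence[UserSnapshot],
                 path: str | Path) -> tuple[Path, Path]:
    """Write ``tweets.jsonl`` and ``users.jsonl`` under directory ``path``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    tweets_path = root / TWEETS_FILE
    users_path = root / USERS_FILE
    write_tweets(tweets, tweets_path)
    write_users(users, users_path)
    return tweets_path, users_path


def read_corpus(path: str | Path) -> tuple[list[TweetRecord], list[UserSnapshot]]:
    root = Path(path)
    return read_tweets(root / TWEETS_FILE), read_users(root / USERS_FILE)
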