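"""Synthetic tweet-corpus generator with planted ground truth.

The original loneliness-disclosure corpus cannot be redistributed, so every
downstream stage is exercised on generated data whose statistical structure
mirrors the real collection: two gendered author populations with planted
lexical markers of configurable effect size, a Poisson daily-posting process
whose intensity steps up by a fixed multiplier at a lockdown date, spam
accounts detectable from their profile posting rate or from decreasing
cumulative status counts, contaminant posts (song lyrics, URLs, retweets,
keyword-matching non-disclosures), ambiguous profile names, and long-tailed
zero-inflated engagement counts.

Every random draw flows through one :class:`numpy.random.Generator` seeded
from the config, so a config + seed pair reproduces the corpus byte for
byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import TweetRecord, UserSnapshot
from .resources import load_name_table, load_default_lyrics, load_stopwords

FEMALE = "female"
MALE = "male"
GENDERS = (FEMALE, MALE)

KEYWORDS = ("lonely", "loneliness")
#: tokens that make a post a recognizable self-disclosure (vs. keyword noise)
DISCLOSURE_CUES = ("feel", "feeling", "tonight", "heart", "empty",
                   "nobody", "wish", "miss", "tired", "aching")
#: tokens typical of keyword-matching posts that are *not* disclosures
NON_DISCLOSURE_CUES = ("song", "lyrics", "listen", "radio", "album",
                       "band", "playlist", "review", "promo", "giveaway")

CONTAMINANT_CLASSES = ("lyric", "url", "retweet", "non_disclosure")

_SYLLABLES = ["ba", "be", "bi", "bo", "bu", "da", "de", "di", "do", "du",
              "ka", "ke", "ki", "ko", "ku", "la", "le", "li", "lo", "lu",
              "ma", "me", "mi", "mo", "mu", "na", "ne", "ni", "no", "nu",
              "pa", "pe", "pi", "po", "pu", "ra", "re", "ri", "ro", "ru",
              "sa", "se", "si", "so", "su", "ta", "te", "ti", "to", "tu",
              "va", "ve", "vi", "vo", "vu", "za", "ze", "zi", "zo", "zu"]


class ConfigError(ValueError):
    """Raised when a GeneratorConfig violates one of its invariants."""


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    return date.fromisoformat(str(value))


@dataclass(frozen=True)
class ContaminantFractions:
    """Proportions of the generated stream taken by each contaminant class."""

    lyric: float = 0.02
    url: float = 0.08
    retweet: float = 0.08
    non_disclosure: float = 0.10

    def as_dict(self) -> dict[str, float]:
        return {"lyric": self.lyric, "url": self.url,
                "retweet": self.retweet, "non_disclosure": self.non_disclosure}

    @property
    def total(self) -> float:
        return self.lyric + self.url + self.retweet + self.non_disclosure


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collection.

    Defaults follow the real study's shape at desk scale: a two-year
    collection window with the lockdown date one year in, a posting-rate
    step of 1.8x at lockdown (the observed near-doubling), planted marker
    vocabularies with a 5x usage ratio between genders, and a spam screen
    boundary at 16 posts/day.
    """

    n_users_per_gender: int = 2000
    study_start: date = date(2019, 3, 15)
    lockdown_date: date = date(2020, 3, 15)
    study_end: date = date(2021, 3, 14)
    base_daily_rate: float = 100.0
    lockdown_multiplier: float = 1.8
    marker_words_per_gender: int = 20
    marker_effect: float = 5.0
    shared_vocab_size: int = 500
    spam_fraction: float = 0.05
    spam_rate_per_day: float = 30.0
    contaminant_fractions: ContaminantFractions = field(
        default_factory=ContaminantFractions)
    ambiguous_name_fraction: float = 0.10
    engagement_tail_exponent: float = 2.5
    outage_dates: tuple[date, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "study_start", _as_date(self.study_start))
        object.__setattr__(self, "lockdown_date", _as_date(self.lockdown_date))
        object.__setattr__(self, "study_end", _as_date(self.study_end))
        object.__setattr__(
            self, "outage_dates",
            tuple(sorted(_as_date(d) for d in self.outage_dates)))
        if isinstance(self.contaminant_fractions, dict):
            object.__setattr__(self, "contaminant_fractions",
                               ContaminantFractions(**self.contaminant_fractions))
        self.validate()

    def validate(self) -> None:
        cf = self.contaminant_fractions
        props = {"spam_fraction": self.spam_fraction,
                 "ambiguous_name_fraction": self.ambiguous_name_fraction,
                 **{f"contaminant_fractions.{k}": v
                    for k, v in cf.as_dict().items()}}
        for name, value in props.items():
            if not (0.0 <= value < 1.0):
                raise ConfigError(f"{name}={value} violates: proportions must lie in [0, 1)")
        if cf.total >= 1.0:
            raise ConfigError(
                f"contaminant fractions sum to {cf.total} violates: jointly < 1")
        if not (self.study_start < self.lockdown_date < self.study_end):
            raise ConfigError(
                "lockdown_date must lie strictly inside (study_start, study_end)")
        if self.marker_effect < 1.0:
            raise ConfigError(f"marker_effect={self.marker_effect} violates: must be >= 1")
        if self.lockdown_multiplier <= 0:
            raise ConfigError("lockdown_multiplier must be > 0")
        if self.n_users_per_gender < 1:
            raise ConfigError("n_users_per_gender must be >= 1")
        if self.base_daily_rate < 0:
            raise ConfigError("base_daily_rate must be >= 0")
        if self.spam_fraction > 0 and self.spam_rate_per_day < 16:
            raise ConfigError(
                f"spam_rate_per_day={self.spam_rate_per_day} violates: must be >= 16 "
                "(the spam screen boundary)")
        n_genuine = self.n_users_per_gender * (1.0 - self.spam_fraction)
        if self.base_daily_rate * self.lockdown_multiplier > n_genuine:
            raise ConfigError(
                "peak daily rate exceeds the genuine user pool; raise "
                "n_users_per_gender or lower base_daily_rate")


@dataclass
class GroundTruth:
    """Planted labels for every generated user and tweet."""

    user_gender: dict[int, str]
    user_is_spam: dict[int, bool]
    user_spam_type: dict[int, str | None]
    user_name_ambiguous: dict[int, bool]
    tweet_is_disclosure: dict[int, bool]
    tweet_contaminant: dict[int, str | None]
    female_markers: tuple[str, ...]
    male_markers: tuple[str, ...]
    pre_intensity: float
    post_intensity: float

    @property
    def spam_user_ids(self) -> set[int]:
        return {u for u, s in self.user_is_spam.items() if s}


def simulate_daily_counts(n_days_pre: int, n_days_post: int,
                          base_rate: float, multiplier: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Daily disclosing-user counts from the step-intensity Poisson process.

    The expected count is ``base_rate`` on each of the ``n_days_pre`` days
    before the lockdown date and ``base_rate * multiplier`` on every day
    from the lockdown date on.
    """
    pre = rng.poisson(base_rate, size=n_days_pre)
    post = rng.poisson(base_rate * multiplier, size=n_days_post)
    return np.concatenate([pre, post])


def _pseudoword(rng: np.random.Generator, n_syllables: int) -> str:
    idx = rng.integers(0, len(_SYLLABLES), size=n_syllables)
    return "".join(_SYLLABLES[i] for i in idx)


def _make_vocabulary(config: GeneratorConfig, rng: np.random.Generator,
                     forbidden: set[str]):
    """Disjoint shared vocabulary and per-gender marker lists."""
    need = config.shared_vocab_size + 2 * config.marker_words_per_gender
    words: list[str] = []
    seen = set(forbidden)
    while len(words) < need:
        w = _pseudoword(rng, 3)
        if w not in seen:
            seen.add(w)
            words.append(w)
    shared = words[:config.shared_vocab_size]
    m = config.marker_words_per_gender
    female_markers = words[config.shared_vocab_size:config.shared_vocab_size + m]
    male_markers = words[config.shared_vocab_size + m:]
    return shared, female_markers, male_markers


def _filler_distribution(shared, stop_pool):
    """Gender-neutral filler vocabulary: shared content words plus a
    stopword pool carrying half the shared weight, so function words are
    realistically frequent."""
    vocab = list(shared) + list(stop_pool)
    n_sh, n_stop = len(shared), len(stop_pool)
    stop_w = 0.5 * n_sh / max(1, n_stop)
    w = np.concatenate([np.full(n_sh, 1.0), np.full(n_stop, stop_w)])
    return vocab, w / w.sum()


def _allocate_marker_slots(n: int, own_markers, other_markers, effect: float,
                           rng: np.random.Generator) -> list[str]:
    """One planted marker per post, by stratified quota.

    Own-gender markers receive ``effect`` times the weight of other-gender
    markers; quotas use largest-remainder rounding and are then randomly
    permuted across the ``n`` posts.  Stratification realizes the planted
    usage-probability ratio tightly even at modest corpus sizes, where iid
    draws would leave the per-marker ratio dominated by sampling noise.
    """
    markers = list(own_markers) + list(other_markers)
    if not markers or n == 0:
        return [""] * n
    weights = np.array([effect] * len(own_markers) + [1.0] * len(other_markers))
    ideal = n * weights / weights.sum()
    counts = np.floor(ideal).astype(int)
    remainder = n - int(counts.sum())
    if remainder > 0:
        frac_order = np.argsort(-(ideal - counts), kind="stable")
        counts[frac_order[:remainder]] += 1
    slots = np.repeat(np.arange(len(markers)), counts)
    slots = rng.permutation(slots)
    return [markers[i] for i in slots]


def _sample_texts(n: int, rng: np.random.Generator, vocab: list[str],
                  probs: np.ndarray, cues: Sequence[str],
                  marker_slots: Sequence[str] | None = None) -> list[str]:
    """Bag-of-words texts: keyword + two class cues + optional planted
    marker + 3-8 filler tokens."""
    if n == 0:
        return []
    lengths = rng.integers(3, 9, size=n)
    flat = rng.choice(len(vocab), size=int(lengths.sum()), p=probs)
    kw = rng.integers(0, len(KEYWORDS), size=n)
    cue = rng.integers(0, len(cues), size=(n, 2))
    texts = []
    pos = 0
    for i in range(n):
        k = int(lengths[i])
        toks = [KEYWORDS[kw[i]], cues[cue[i, 0]], cues[cue[i, 1]]]
        if marker_slots is not None and marker_slots[i]:
            toks.append(marker_slots[i])
        toks += [vocab[j] for j in flat[pos:pos + k]]
        pos += k
        texts.append(" ".join(toks))
    return texts


def _day_ts(day: date, second: int) -> datetime:
    return datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + \
        timedelta(seconds=int(second))


def _status_count(rate: float, created: datetime, when: datetime) -> int:
    age_days = (when - created).total_seconds() / 86400.0
    return max(0, int(round(rate * age_days)))


def generate_corpus(config: GeneratorConfig):
    """Generate ``(tweets, users, ground_truth)`` for one study condition.

    Disclosing users per gender per day follow the step-intensity Poisson
    process of :func:`simulate_daily_counts`; each selected user posts one
    disclosure that day.  Contaminant posts are layered on top at rates that
    make their expected share of the total stream equal the configured
    fractions.  Collection-outage days are dropped after generation, as a
    real stream outage would drop them.
    """
    rng = np.random.default_rng(config.seed)
    stopwords = sorted(load_stopwords())
    lyric_phrases = load_default_lyrics()
    forbidden = set(stopwords) | set(KEYWORDS) | set(DISCLOSURE_CUES) | \
        set(NON_DISCLOSURE_CUES)
    shared, f_markers, m_markers = _make_vocabulary(config, rng, forbidden)
    stop_pool = stopwords[:40]
    vocab, filler_probs = _filler_distribution(shared, stop_pool)

    name_table = load_name_table()
    unambiguous = {g: sorted(n for n, gs in name_table.items() if gs == {code})
                   for g, code in ((FEMALE, "F"), (MALE, "M"))}
    ambiguous_names = sorted(n for n, gs in name_table.items() if len(gs) > 1)

    days = [config.study_start + timedelta(days=i)
            for i in range((config.study_end - config.study_start).days + 1)]
    n_pre = sum(1 for d in days if d < config.lockdown_date)
    n_post = len(days) - n_pre

    # ---- users -------------------------------------------------------------
    users: dict[int, dict] = {}
    genuine_ids = {FEMALE: [], MALE: []}
    spam_specs: list[dict] = []
    uid = 1
    n_spam = int(round(config.spam_fraction * config.n_users_per_gender))
    n_ambig = int(round(config.ambiguous_name_fraction * config.n_users_per_gender))
    for gender in GENDERS:
        pool = unambiguous[gender]
        for i in range(config.n_users_per_gender):
            is_spam = i < n_spam
            is_ambig = n_spam <= i < n_spam + n_ambig if not is_spam else False
            # spam accounts keep unambiguous names so the gender stage
            # does not pre-empt the activity filter
            if is_ambig and ambiguous_names:
                given = ambiguous_names[int(rng.integers(0, len(ambiguous_names)))]
            else:
                given = pool[int(rng.integers(0, len(pool)))]
            surname = chr(ord("a") + int(rng.integers(0, 26))).upper()
            display = f"{given.capitalize()} {surname}."
            created = datetime(2010, 1, 1, tzinfo=timezone.utc) + timedelta(
                days=float(rng.uniform(0, 3000)))
            if created.date() >= config.study_start:
                created = datetime(config.study_start.year - 1, 1, 1,
                                   tzinfo=timezone.utc)
            if is_spam:
                spam_type = "rate" if (i % 2 == 0) else "decreasing"
                rate = float(rng.uniform(max(16.0, config.spam_rate_per_day),
                                         config.spam_rate_per_day * 1.5)) \
                    if spam_type == "rate" else float(rng.uniform(1.0, 4.0))
                spam_specs.append({"id": uid, "gender": gender,
                                   "type": spam_type, "rate": rate})
            else:
                spam_type = None
                rate = float(rng.uniform(0.2, 7.5))
                genuine_ids[gender].append(uid)
            users[uid] = {"gender": gender, "name": display, "given": given,
                          "created": created, "rate": rate,
                          "is_spam": is_spam, "spam_type": spam_type,
                          "is_ambig": bool(is_ambig)}
            uid += 1

    # ---- tweets ------------------------------------------------------------
    tweets_raw: list[dict] = []  # class/author/day records, text filled later
    cf = config.contaminant_fractions
    contam_scale = 1.0 / (1.0 - cf.total) if cf.total > 0 else 1.0
    for gender in GENDERS:
        counts = simulate_daily_counts(n_pre, n_post, config.base_daily_rate,
                                       config.lockdown_multiplier, rng)
        pool = np.array(genuine_ids[gender])
        for di, day in enumerate(days):
            k = min(int(counts[di]), len(pool))
            if k > 0:
                authors = rng.choice(pool, size=k, replace=False)
                seconds = rng.integers(0, 86400, size=k)
                for a, s in zip(authors, seconds):
                    tweets_raw.append({"cls": None, "author": int(a),
                                       "day": day, "sec": int(s),
                                       "gender": gender})
            day_rate = config.base_daily_rate * (
                config.lockdown_multiplier if day >= config.lockdown_date else 1.0)
            for cls, frac in cf.as_dict().items():
                if frac <= 0:
                    continue
                m = int(rng.poisson(day_rate * frac * contam_scale))
                if m == 0:
                    continue
                authors = rng.choice(pool, size=m, replace=True)
                seconds = rng.integers(0, 86400, size=m)
                for a, s in zip(authors, seconds):
                    tweets_raw.append({"cls": cls, "author": int(a),
                                       "day": day, "sec": int(s),
                                       "gender": gender})
    # spam users post a few disclosure-looking tweets; scheduled on
    # non-outage days so planted spam stays observable in the collection
    outage_set = set(config.outage_dates)
    observable = [i for i, d in enumerate(days) if d not in outage_set]
    for spec in spam_specs:
        n_tw = int(2 + rng.poisson(1.0)) if spec["type"] == "decreasing" \
            else int(1 + rng.poisson(1.0))
        day_idx = np.sort(rng.choice(observable, size=n_tw, replace=True))
        seconds = np.sort(rng.integers(0, 86400, size=n_tw))
        for j, (di, s) in enumerate(zip(day_idx, seconds)):
            tweets_raw.append({"cls": "spam", "author": spec["id"],
                               "day": days[int(di)], "sec": int(s),
                               "gender": spec["gender"], "spam_seq": j})

    # texts per (gender, class) batch, in a fixed order for determinism
    url_counter = 1
    by_batch: dict[tuple[str, str | None], list[int]] = {}
    for idx, t in enumerate(tweets_raw):
        by_batch.setdefault((t["gender"], t["cls"]), []).append(idx)
    for gender in GENDERS:
        for cls in (None, "lyric", "url", "retweet", "non_disclosure", "spam"):
            idxs = by_batch.get((gender, cls), [])
            if not idxs:
                continue
            own, other = (f_markers, m_markers) if gender == FEMALE \
                else (m_markers, f_markers)
            if cls == "lyric":
                pick = rng.integers(0, len(lyric_phrases), size=len(idxs))
                texts = [lyric_phrases[i] for i in pick]
            else:
                slots = _allocate_marker_slots(
                    len(idxs), own, other, config.marker_effect, rng)
                cues = NON_DISCLOSURE_CUES if cls == "non_disclosure" \
                    else DISCLOSURE_CUES
                texts = _sample_texts(len(idxs), rng, vocab, filler_probs,
                                      cues, slots)
            for i, text in zip(idxs, texts):
                t = tweets_raw[i]
                if cls == "url":
                    link = f"https://t.co/x{url_counter:06d}"
                    url_counter += 1
                    t["text"] = f"{text} {link}"
                    t["urls"] = (link,)
                elif cls == "retweet":
                    t["text"] = f"rt @user{t['author']}: {text}"
                    t["retweeted"] = True
                else:
                    t["text"] = text

    # engagement: zero-inflated discrete power law (zipf tail)
    n_all = len(tweets_raw)
    zero_inflation = {"reply_count": 0.60, "retweet_count": 0.70,
                      "like_count": 0.45, "quote_count": 0.85}
    engagement = {}
    for metric, z in zero_inflation.items():
        nonzero = rng.random(n_all) >= z
        counts = np.zeros(n_all, dtype=int)
        counts[nonzero] = rng.zipf(config.engagement_tail_exponent,
                                   size=int(nonzero.sum()))
        engagement[metric] = counts

    # assemble records in chronological order
    order = sorted(range(n_all),
                   key=lambda i: (tweets_raw[i]["day"], tweets_raw[i]["sec"], i))
    outage = set(config.outage_dates)
    tweets: list[TweetRecord] = []
    tweet_truth_label: dict[int, bool] = {}
    tweet_truth_class: dict[int, str | None] = {}
    deleter_base: dict[int, int] = {}
    deleter_last: dict[int, int] = {}
    tid = 1
    for i in order:
        t = tweets_raw[i]
        if t["day"] in outage:
            continue
        u = users[t["author"]]
        when = _day_ts(t["day"], t["sec"])
        if u["spam_type"] == "decreasing":
            if t["author"] not in deleter_base:
                deleter_base[t["author"]] = max(
                    200, _status_count(u["rate"], u["created"], when)) + 5000
            statuses = max(0, deleter_base[t["author"]] - 50 * t.get("spam_seq", 0))
            deleter_last[t["author"]] = statuses
        else:
            statuses = _status_count(u["rate"], u["created"], when)
        snap = UserSnapshot(id=t["author"], name=u["name"],
                            created_at=u["created"], statuses_count=statuses)
        tweets.append(TweetRecord(
            id=tid, created_at=when, text=t["text"], lang="en", user=snap,
            retweeted=bool(t.get("retweeted", False)),
            urls=tuple(t.get("urls", ())),
            reply_count=int(engagement["reply_count"][i]),
            retweet_count=int(engagement["retweet_count"][i]),
            like_count=int(engagement["like_count"][i]),
            quote_count=int(engagement["quote_count"][i]),
        ))
        cls = t["cls"]
        # URL/retweet posts are disclosures excluded for provenance; spam
        # posts read as disclosures (that is why the rate screen exists);
        # lyric and keyword-noise posts are not disclosures at all
        tweet_truth_label[tid] = cls in (None, "url", "retweet", "spam")
        tweet_truth_class[tid] = cls
        tid += 1

    end_ts = datetime(config.study_end.year, config.study_end.month,
                      config.study_end.day, 23, 59, 59, tzinfo=timezone.utc)
    user_snapshots = []
    for u_id in sorted(users):
        u = users[u_id]
        if u["spam_type"] == "decreasing" and u_id in deleter_last:
            statuses = deleter_last[u_id]
        else:
            statuses = _status_count(u["rate"], u["created"], end_ts)
        user_snapshots.append(UserSnapshot(
            id=u_id, name=u["name"], created_at=u["created"],
            statuses_count=statuses))

    truth = GroundTruth(
        user_gender={u_id: users[u_id]["gender"] for u_id in sorted(users)},
        user_is_spam={u_id: users[u_id]["is_spam"] for u_id in sorted(users)},
        user_spam_type={u_id: users[u_id]["spam_type"] for u_id in sorted(users)},
        user_name_ambiguous={u_id: users[u_id]["is_ambig"] for u_id in sorted(users)},
        tweet_is_disclosure=tweet_truth_label,
        tweet_contaminant=tweet_truth_class,
        female_markers=tuple(f_markers),
        male_markers=tuple(m_markers),
        pre_intensity=config.base_daily_rate,
        post_intensity=config.base_daily_rate * config.lockdown_multiplier,
    )
    return tweets, user_snapshots, truth


GROUND_TRUTH_FILE = "ground_truth.jsonl"


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """JSON-Lines dump: one meta line, then one line per user and per tweet."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        meta = {"kind": "meta",
                "female_markers": list(truth.female_markers),
                "male_markers": list(truth.male_markers),
                "pre_intensity": truth.pre_intensity,
                "post_intensity": truth.post_intensity}
        fh.write(json.dumps(meta, separators=(",", ":")) + "\n")
        for u_id in sorted(truth.user_gender):
            fh.write(json.dumps({
                "kind": "user", "id": u_id,
                "gender": truth.user_gender[u_id],
                "is_spam": truth.user_is_spam[u_id],
                "spam_type": truth.user_spam_type[u_id],
                "name_ambiguous": truth.user_name_ambiguous[u_id],
            }, separators=(",", ":")) + "\n")
        for t_id in sorted(truth.tweet_is_disclosure):
            fh.write(json.dumps({
                "kind": "tweet", "id": t_id,
                "is_disclosure": truth.tweet_is_disclosure[t_id],
                "contaminant": truth.tweet_contaminant[t_id],
            }, separators=(",", ":")) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    meta = None
    user_gender, user_is_spam, user_spam_type, user_ambig = {}, {}, {}, {}
    tweet_label, tweet_class = {}, {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            kind = obj.get("kind")
            if kind == "meta":
                meta = obj
            elif kind == "user":
                user_gender[obj["id"]] = obj["gender"]
                user_is_spam[obj["id"]] = obj["is_spam"]
                user_spam_type[obj["id"]] = obj["spam_type"]
                user_ambig[obj["id"]] = obj["name_ambiguous"]
            elif kind == "tweet":
                tweet_label[obj["id"]] = obj["is_disclosure"]
                tweet_class[obj["id"]] = obj["contaminant"]
    if meta is None:
        raise ValueError(f"{path}: missing ground-truth meta line")
    return GroundTruth(
        user_gender=user_gender, user_is_spam=user_is_spam,
        user_spam_type=user_spam_type, user_name_ambiguous=user_ambig,
        tweet_is_disclosure=tweet_label, tweet_contaminant=tweet_class,
        female_markers=tuple(meta["female_markers"]),
        male_markers=tuple(meta["male_markers"]),
        pre_intensity=float(meta["pre_intensity"]),
        post_intensity=float(meta["post_intensity"]),
    )
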